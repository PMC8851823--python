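import numpy as np
import pandas as pd
import pytest

from kinreject import (
    ErrorModel,
    adjusted_error_rate,
    fit_group,
    flag_failing_snps,
    maf_stratified_report,
    pairwise_rejections,
    rejection_detection_prob,
    snp_rejection_counts,
    snp_summaries,
)
from kinreject.error_analysis import DegenerateLocusError
from kinreject.synthetic import SimConfig, inject_errors, simulate


def genotyped_parent_pairs(truth):
    """True parent-offspring pairs whose parent is among the candidates."""
    pairs = []
    for row in truth.pedigree.itertuples(index=False):
        if row.sire_genotyped:
            pairs.append((row.sire_id, row.offspring_id))
        if row.dam_genotyped:
            pairs.append((row.dam_id, row.offspring_id))
    return pairs


def enumerate_rejection_prob(p, e, model, p_other=None):
    """Exact P(opposing homozygotes) for a parent-offspring pair.

    Full enumeration over the parent's HWE genotype, its transmitted allele,
    the other pool's allele, and both calls' miscall channels.
    """
    po = p if p_other is None else p_other
    q, qo = 1 - p, 1 - po

    def channels(g):
        if model is ErrorModel.GENOTYPE_UNIFORM:
            others = [x for x in (0, 1, 2) if x != g]
            return [(g, 1 - e)] + [(o, e / 2) for o in others]
        f = e / 2
        if g == 1:
            return [(1, (1 - f) ** 2 + f * f), (0, f * (1 - f)), (2, f * (1 - f))]
        return [(g, (1 - f) ** 2), (1, 2 * f * (1 - f)), (2 - g, f * f)]

    total = 0.0
    for gp, w_gp in ((0, q * q), (1, 2 * p * q), (2, p * p)):
        for ta, w_ta in ((1, gp / 2), (0, 1 - gp / 2)):
            for ob, w_ob in ((1, po), (0, qo)):
                go = ta + ob
                for gp_obs, w1 in channels(gp):
                    for go_obs, w2 in channels(go):
                        if {gp_obs, go_obs} == {0, 2}:
                            total += w_gp * w_ta * w_ob * w1 * w2
    return total


class TestRejectionDetectionProb:
    def test_allele_label_symmetry(self):
        for model in ErrorModel:
            assert rejection_detection_prob(0.3, model) == pytest.approx(
                rejection_detection_prob(0.7, model))

    def test_degenerate_frequency_raises(self):
        with pytest.raises(DegenerateLocusError):
            rejection_detection_prob(0.0)

    @pytest.mark.parametrize("model", list(ErrorModel))
    @pytest.mark.parametrize("p,p_other", [(0.3, None), (0.5, None),
                                           (0.1, 0.8), (0.9, 0.2)])
    def test_closed_form_matches_enumeration(self, model, p, p_other):
        # the closed form is the first-order coefficient in tau = e*c(p)
        e = 1e-4
        exact = enumerate_rejection_prob(p, e, model, p_other)
        c = rejection_detection_prob(p, model, p_other)
        assert exact / e == pytest.approx(c, abs=5e-3 * max(c, 1e-3))

    def test_known_values_equal_pools(self):
        p = 0.3
        assert rejection_detection_prob(p, ErrorModel.GENOTYPE_UNIFORM) == \
            pytest.approx(p * p + 0.7 * 0.7)
        assert rejection_detection_prob(p, ErrorModel.ALLELE_FLIP) == \
            pytest.approx(p * 0.7)

    def test_monte_carlo_rate_at_half(self, rng):
        p, e, n_loci = 0.5, 0.01, 200_000
        parent = rng.binomial(2, p, n_loci)
        off = (rng.random(n_loci) < parent / 2).astype(np.int8) \
            + rng.binomial(1, p, n_loci).astype(np.int8)
        obs_p, _ = inject_errors(parent[None, :].astype(np.int8), e,
                                 ErrorModel.GENOTYPE_UNIFORM, rng)
        obs_o, _ = inject_errors(off[None, :], e,
                                 ErrorModel.GENOTYPE_UNIFORM, rng)
        rate = (((obs_p == 0) & (obs_o == 2))
                | ((obs_p == 2) & (obs_o == 0))).mean()
        expect = enumerate_rejection_prob(p, e, ErrorModel.GENOTYPE_UNIFORM)
        se = np.sqrt(expect * (1 - expect) / n_loci)
        assert abs(rate - expect) <= 3 * se


class TestSnpRejectionCounts:
    def test_zero_error_simulation_all_zero(self, clean_sim):
        g, _, truth = clean_sim
        profiles = snp_rejection_counts(g, genotyped_parent_pairs(truth))
        assert (profiles["n_rejections"] == 0).all()

    def test_forced_wrong_genotype_matches_bruteforce(self, clean_sim):
        g, _, truth = clean_sim
        j = 17
        calls = g.calls.copy()
        off_rows = [g.sample_index(o) for o in truth.pedigree["offspring_id"]]
        calls[off_rows, j] = 0  # every offspring forced hom-alt at SNP j
        forced = type(g)(g.samples, g.snps, calls)
        pairs = genotyped_parent_pairs(truth)
        profiles = snp_rejection_counts(forced, pairs)
        brute = sum(
            1 for par, off in pairs
            if {int(calls[forced.sample_index(par), j]),
                int(calls[forced.sample_index(off), j])} == {0, 2}
        )
        assert profiles.loc[j, "n_rejections"] == brute
        assert brute == sum(
            1 for par, _ in pairs if calls[forced.sample_index(par), j] == 2)

    def test_conservation_identity(self, small_sim):
        g, roles, truth = small_sim
        pairs = genotyped_parent_pairs(truth)
        profiles = snp_rejection_counts(g, pairs)
        rej = pairwise_rejections(g, roles)
        lookup = {frozenset((r.sample_i, r.sample_j)): r.delta
                  for r in rej.itertuples(index=False)}
        total_delta = sum(lookup[frozenset(p)] for p in pairs)
        assert profiles["n_rejections"].sum() == total_delta


class TestFlagFailingSnps:
    @pytest.mark.parametrize("count,failing", [(4, False), (5, True), (6, True)])
    def test_threshold_boundary(self, count, failing):
        profiles = pd.DataFrame({"snp_id": ["a"], "maf": [0.2],
                                 "n_rejections": [count]})
        assert flag_failing_snps(profiles, 5)["failing"].iloc[0] == failing

    def test_matches_bruteforce_filter(self, rng):
        counts = rng.integers(0, 12, 300)
        profiles = pd.DataFrame({"snp_id": [f"s{i}" for i in range(300)],
                                 "maf": 0.2, "n_rejections": counts})
        out = flag_failing_snps(profiles, 5)
        assert out["failing"].sum() == (counts >= 5).sum()


class TestAdjustedErrorRate:
    def test_zero_tau_g_gives_zero(self):
        summ = pd.DataFrame({"maf": [0.1, 0.3, 0.5]})
        est = adjusted_error_rate(0.0, summ)
        assert est.adjusted_error == 0.0

    def test_round_trip_recovers_injected_error(self):
        # common-pool cross, genotype-uniform miscalls at 0.6%
        cfg = SimConfig(
            n_sires=4, n_dams=30, n_offspring=60, n_snps=20_000,
            sire_breed_freqs={"dist": "uniform", "low": 0.05, "high": 0.95},
            dam_breed_freqs={"dist": "shared"},
            error_rate=0.006, missing_rate=0.0, n_duplicate_samples=0,
            n_failing_snps=0, unrelated_parent_fraction=0.3, seed=5,
        )
        g, roles, truth = simulate(cfg)
        rej = pairwise_rejections(g, roles)
        parent = rej[rej["group"].isin(("DAM_OFF", "SIRE_OFF"))]
        fitted, fit = fit_group(parent)
        parents = [s for s in g.samples if roles[s] in ("SIRE", "DAM")]
        summ = snp_summaries(g.subset_samples(parents))
        est = adjusted_error_rate(fit.tau_g, summ, ErrorModel.GENOTYPE_UNIFORM)
        assert abs(est.adjusted_error - 0.006) / 0.006 < 0.15

    def test_adjusted_never_below_lower_bound(self, rng):
        summ = pd.DataFrame({"maf": rng.uniform(0.01, 0.5, 200)})
        for model in ErrorModel:
            est = adjusted_error_rate(1e-3, summ, model)
            assert est.adjusted_error >= est.tau_g_lower_bound
            assert 0 < est.detection_factor < 1

    def test_maf_shift_direction_is_model_dependent(self):
        high = pd.DataFrame({"maf": np.full(100, 0.4)})
        low = pd.DataFrame({"maf": np.full(100, 0.02)})
        tau_g = 1e-3
        # allele-flip errors: low-MAF SNPs rarely expose a miscall, so the
        # same observed tau_g implies a larger underlying error rate
        e_low = adjusted_error_rate(tau_g, low, ErrorModel.ALLELE_FLIP)
        e_high = adjusted_error_rate(tau_g, high, ErrorModel.ALLELE_FLIP)
        assert e_low.adjusted_error > e_high.adjusted_error
        # genotype-uniform errors: detection approaches certainty at low MAF
        u_low = adjusted_error_rate(tau_g, low, ErrorModel.GENOTYPE_UNIFORM)
        u_high = adjusted_error_rate(tau_g, high, ErrorModel.GENOTYPE_UNIFORM)
        assert u_low.adjusted_error < u_high.adjusted_error


class TestMafStratifiedReport:
    def test_printed_proportions(self):
        maf = np.full(546_220, 0.3)
        maf[:122_615] = 0.01
        summaries = pd.DataFrame({"maf": maf})
        rej = np.zeros(546_220, dtype=int)
        # rejecting SNPs: 165 below the cut, 7,579 above
        rej[:165] = 1
        rej[122_615:122_615 + 7_744 - 165] = 1
        profiles = pd.DataFrame({"maf": maf, "n_rejections": rej})
        report = maf_stratified_report(profiles, summaries, 0.05)
        by = report.set_index("stratum")["proportion"]
        assert round(by["all_snps"], 3) == 0.224
        assert round(by["rejecting_snps"], 3) == 0.021

    def test_empty_rejecting_set_undefined(self):
        summaries = pd.DataFrame({"maf": [0.1, 0.2]})
        profiles = pd.DataFrame({"maf": [0.1, 0.2], "n_rejections": [0, 0]})
        report = maf_stratified_report(profiles, summaries)
        assert np.isnan(
            report.set_index("stratum").loc["rejecting_snps", "proportion"])

    def test_low_maf_depletion_under_allele_flip(self):
        cfg = SimConfig(
            n_sires=4, n_dams=20, n_offspring=60, n_snps=15_000,
            sire_breed_freqs={"dist": "beta", "a": 0.4, "b": 0.4},
            dam_breed_freqs={"dist": "beta", "a": 0.4, "b": 0.4},
            error_rate=0.02, error_model=ErrorModel.ALLELE_FLIP,
            missing_rate=0.0, n_duplicate_samples=0, n_failing_snps=0,
            unrelated_parent_fraction=0.0, seed=13,
        )
        g, _, truth = simulate(cfg)
        profiles = snp_rejection_counts(g, genotyped_parent_pairs(truth))
        report = maf_stratified_report(profiles, snp_summaries(g), 0.05)
        by = report.set_index("stratum")["proportion"]
        assert by["rejecting_snps"] < by["all_snps"]
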