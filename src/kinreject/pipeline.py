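"""End-to-end workflow: pairs -> per-group EM -> parentage -> error report.

Mirrors how the analysis is run on a real crossbreeding dataset: compute all
pairwise rejection statistics, screen for duplicate samples, fit the
two-component mixture within the dam-offspring and sire-offspring groups
(and the offspring-offspring group, whose assignments are only "full-sib
candidates" because half-sibs of related parents contaminate that
component), resolve maternity/paternity conflicts via the duplicate list,
then profile per-SNP rejections among verified pairs and estimate the
genotyping error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .error_analysis import (
    ErrorModel,
    adjusted_error_rate,
    flag_failing_snps,
    maf_stratified_report,
    snp_rejection_counts,
)
from .exclusion import detect_duplicates, pairwise_rejections
from .genotype_io import (
    GenotypeMatrix,
    SampleRoles,
    filter_snps,
    read_dosage_table,
    read_roles,
    read_vcf,
    snp_summaries,
)
from .mixture import SingleModeError, fit_group

logger = logging.getLogger(__name__)

PARENT_GROUPS = ("DAM_OFF", "SIRE_OFF")


@dataclass
class RunConfig:
    """Settings of a full pipeline run."""

    vcf: str | Path | None = None
    dosage_table: str | Path | None = None
    dosage_map: str | Path | None = None
    roles_path: str | Path | None = None
    out_dir: str | Path = "kinreject_out"
    min_call_rate: float = 0.97
    chromosomes: frozenset[str] | None = None
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    assign_threshold: float = 0.5
    use_gamma_weights: bool = False
    failing_threshold: int = 5
    error_model: ErrorModel = ErrorModel.GENOTYPE_UNIFORM
    # duplicates of one sample each miscalled at rate e agree at ~(1-e)^2 of
    # loci, so 0.99 misses duplicates once e > 0.5%; 0.98 tolerates e ~ 1%
    # while staying far above first-degree concordance (~0.6-0.8)
    duplicate_threshold: float = 0.98
    collapse_duplicates: bool = True
    drop_failing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.error_model = ErrorModel(self.error_model)


def load_inputs(config: RunConfig) -> tuple[GenotypeMatrix, SampleRoles]:
    if config.vcf is not None:
        g = read_vcf(config.vcf)
    elif config.dosage_table is not None and config.dosage_map is not None:
        g = read_dosage_table(config.dosage_table, config.dosage_map)
    else:
        raise ValueError("need either vcf or dosage_table + dosage_map")
    if config.roles_path is None:
        raise ValueError("roles_path is required")
    roles = read_roles(config.roles_path)
    roles.validate_against(g)
    return g, roles


def run_full(
    config: RunConfig,
    genotypes: GenotypeMatrix | None = None,
    roles: SampleRoles | None = None,
) -> dict:
    """Run the whole workflow and write its report files.

    ``genotypes``/``roles`` may be passed directly (e.g. straight from the
    simulator) to skip file input.  Returns the summary dictionary that is
    also written to ``summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genotypes is None or roles is None:
        genotypes, roles = load_inputs(config)

    g = filter_snps(genotypes, config.min_call_rate, config.chromosomes)
    logger.info("kept %d of %d SNPs after filtering", g.n_snps, genotypes.n_snps)

    pairs = pairwise_rejections(g, roles)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)

    dups = detect_duplicates(g, config.duplicate_threshold)
    dups.to_csv(out / "duplicates.tsv", sep="\t", index=False)
    dup_pairs = list(zip(dups["sample_i"], dups["sample_j"]))
    dropped: set[str] = set()
    if config.collapse_duplicates:
        for a, b in dup_pairs:  # keep the first-seen copy
            if a not in dropped:
                dropped.add(b)
    em_pairs = pairs[~(pairs["sample_i"].isin(dropped)
                       | pairs["sample_j"].isin(dropped))]

    fits: dict[str, object] = {}
    assigned_frames = []
    for grp in ("DAM_OFF", "SIRE_OFF", "OFF_OFF"):
        sub = em_pairs[em_pairs["group"] == grp]
        if len(sub) < 2:
            logger.warning("group %s has %d pairs; EM skipped", grp, len(sub))
            continue
        try:
            annotated, fit = fit_group(
                em_pairs, grp,
                tol=config.em_tol, max_iter=config.em_max_iter,
                use_gamma_weights=config.use_gamma_weights,
                assign_threshold=config.assign_threshold,
            )
        except SingleModeError:
            logger.warning("group %s has a single mode; EM skipped", grp)
            continue
        fits[grp] = fit
        annotated.to_csv(out / f"fit_{grp}.tsv", sep="\t", index=False)
        with open(out / f"fit_{grp}.json", "w") as fh:
            json.dump({
                "group": grp,
                "tau_g": fit.tau_g, "tau_r": fit.tau_r, "gamma": fit.gamma,
                "n_iter": fit.n_iter, "converged": fit.converged,
                "collapsed": fit.collapsed,
                "full_sib_candidate_caveat": grp == "OFF_OFF",
                "trace": fit.trace.to_dict(orient="records"),
            }, fh, indent=2, sort_keys=True)
        assigned_frames.append(annotated)

    assignments = (pd.concat(assigned_frames, ignore_index=True)
                   if assigned_frames else pd.DataFrame(
                       columns=list(pairs.columns) + ["responsibility", "assigned"]))
    assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)

    parentage, conflicts = _parentage_table(assignments, roles, dup_pairs)
    parentage.to_csv(out / "parentage.tsv", sep="\t", index=False)

    # per-SNP profile over verified parent-offspring pairs
    verified = assignments[
        assignments["group"].isin(PARENT_GROUPS) & assignments["assigned"]]
    verified_pairs = list(zip(verified["sample_i"], verified["sample_j"]))
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": g.n_samples,
        "n_snps": g.n_snps,
        "n_pairs": len(pairs),
        "n_duplicate_pairs": len(dup_pairs),
        "n_verified_parent_offspring": len(verified_pairs),
        "paternities": int(parentage["sire_id"].notna().sum()),
        "maternities": int(parentage["dam_id"].notna().sum()),
        "both_parents": int((parentage["sire_id"].notna()
                             & parentage["dam_id"].notna()).sum()),
        "parent_conflicts": conflicts,
        "groups_fitted": sorted(fits),
    }
    for grp, fit in fits.items():
        summary[f"tau_g_{grp}"] = fit.tau_g
        summary[f"tau_r_{grp}"] = fit.tau_r
        summary[f"gamma_{grp}"] = fit.gamma

    if verified_pairs:
        profiles = snp_rejection_counts(g, verified_pairs)
        profiles = flag_failing_snps(profiles, config.failing_threshold)
        profiles.to_csv(out / "snp_rejections.tsv", sep="\t", index=False)
        summary["n_rejections_total"] = int(profiles["n_rejections"].sum())
        summary["n_rejecting_snps"] = int((profiles["n_rejections"] > 0).sum())
        summary["n_failing_snps"] = int(profiles["failing"].sum())

        tau_g_joint = _joint_tau_g(verified)
        parent_samples = [s for s in g.samples
                         if roles[s] in ("SIRE", "DAM") and s not in dropped]
        summ = snp_summaries(g.subset_samples(parent_samples))
        est = adjusted_error_rate(tau_g_joint, summ, config.error_model)
        with open(out / "error_estimate.json", "w") as fh:
            json.dump(est.to_dict() | {"tau_g_joint": tau_g_joint},
                      fh, indent=2, sort_keys=True)
        summary["tau_g_joint"] = tau_g_joint
        summary["adjusted_error"] = est.adjusted_error
        summary["detection_factor"] = est.detection_factor
        report = maf_stratified_report(profiles, snp_summaries(g))
        report.to_csv(out / "maf_report.tsv", sep="\t", index=False)
        if config.drop_failing:
            keep = ~g.snps["snp_id"].isin(
                profiles.loc[profiles["failing"], "snp_id"]).to_numpy()
            filter_snps(g.subset_snps(keep)).snps.to_csv(
                out / "snps_after_drop.tsv", sep="\t", index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _joint_tau_g(verified: pd.DataFrame) -> float:
    """Pooled error-component rate over both parent-offspring groups.

    Delta-weighted mean of delta/n_eff over verified pairs, i.e. the M-step
    estimator restricted to the accepted component with hard weights.
    Falls back to the plain mean rate when no verified pair has a rejection.
    """
    d = verified["delta"].to_numpy(dtype=float)
    n = verified["n_eff"].to_numpy(dtype=float)
    if d.sum() == 0:
        return float((d / n).mean())
    return float((d * (d / n)).sum() / d.sum())


def _parentage_table(
    assignments: pd.DataFrame,
    roles: SampleRoles,
    dup_pairs: list[tuple[str, str]],
) -> tuple[pd.DataFrame, int]:
    """One row per offspring with its assigned sire and dam, if any.

    An offspring with two assigned dams (or sires) is checked against the
    duplicate list first: if the two are copies of one individual the
    first-seen identifier is kept; otherwise both are reported as a conflict.
    """
    dup_map: dict[str, str] = {}
    for a, b in dup_pairs:
        dup_map[b] = dup_map.get(a, a)

    def canonical(s: str) -> str:
        return dup_map.get(s, s)

    by_off: dict[str, dict[str, set]] = {}
    parent_role = {"DAM_OFF": "dam_id", "SIRE_OFF": "sire_id"}
    sub = assignments[assignments["group"].isin(parent_role) & assignments["assigned"]]
    for row in sub.itertuples(index=False):
        off, par = ((row.sample_i, row.sample_j)
                    if roles[row.sample_i] == "OFFSPRING"
                    else (row.sample_j, row.sample_i))
        slot = parent_role[row.group]
        by_off.setdefault(off, {"sire_id": set(), "dam_id": set()})
        by_off[off][slot].add(canonical(par))

    rows, conflicts = [], 0
    for off in sorted(by_off):
        rec = {"offspring_id": off, "sire_id": None, "dam_id": None,
               "sire_conflict": "", "dam_conflict": ""}
        for slot in ("sire_id", "dam_id"):
            cands = sorted(by_off[off][slot])
            if len(cands) == 1:
                rec[slot] = cands[0]
            elif len(cands) > 1:
                conflicts += 1
                rec[slot.replace("_id", "_conflict")] = ";".join(cands)
        rows.append(rec)
    cols = ["offspring_id", "sire_id", "dam_id", "sire_conflict", "dam_conflict"]
    return pd.DataFrame(rows, columns=cols), conflicts
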