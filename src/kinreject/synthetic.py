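"""Synthetic crossbred pedigrees and genotypes with known ground truth.

The generator emulates a two-breed terminal cross genotyped on a dense SNP
array: candidate sires from one breed, dams from another with divergent
allele frequencies, and crossbred offspring produced by strict Mendelian
transmission.  On top of the clean genotypes it layers the nuisances the
analysis has to survive:

* per-genotype miscalls at rate ``e`` under a configurable error model,
* missing calls,
* duplicate samples (the same pre-error individual re-corrupted with fresh
  error draws, as when one animal's blood is submitted twice),
* systematically failing SNPs (forced homozygotes, random calls, or
  shuffled columns),
* offspring whose true parents are not among the genotyped candidates
  (drawn from hidden same-breed pools), so that only a fraction of
  parentages is resolvable.

Defaults follow the crossbreeding design this tool was built around: nine
candidate sires, 55 dams, 214 offspring, a 0.6 unresolvable-parent
fraction, two duplicated dams, twenty failing SNPs, and a 0.006 miscall
rate, at 50,000 SNPs.  Loci are independent (the statistic is single-SNP;
no linkage is simulated).  Everything is driven by one integer-seeded
generator, so a fixed seed reproduces the dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .error_analysis import ErrorModel
from .genotype_io import MISSING, GenotypeMatrix, SampleRoles

#: Frequency regimes: divergent breeds reproduce the large sire-dam
#: rejection rates of a cross; a common pool (dam spec "shared" reuses the
#: sire pool's per-SNP frequencies) gives a single-population null design.
DIVERGENT_SIRE_FREQS = {"dist": "beta", "a": 5.0, "b": 2.0}
DIVERGENT_DAM_FREQS = {"dist": "beta", "a": 2.0, "b": 5.0}
COMMON_POOL_FREQS = {"dist": "uniform", "low": 0.05, "high": 0.95}
SHARED_POOL = {"dist": "shared"}

FAILING_MODES = ("force_hom", "random_call", "shuffle")


@dataclass
class SimConfig:
    """Parameters of one simulated crossbreeding experiment."""

    n_sires: int = 9
    n_dams: int = 55
    n_offspring: int = 214
    n_snps: int = 50_000
    sire_breed_freqs: dict = field(default_factory=lambda: dict(DIVERGENT_SIRE_FREQS))
    dam_breed_freqs: dict = field(default_factory=lambda: dict(DIVERGENT_DAM_FREQS))
    error_rate: float = 0.006
    error_model: ErrorModel = ErrorModel.GENOTYPE_UNIFORM
    missing_rate: float = 0.01
    n_duplicate_samples: int = 2
    n_failing_snps: int = 20
    failing_mode: str = "force_hom"
    failing_snps: list[tuple[int, str]] | None = None
    unrelated_parent_fraction: float = 0.6
    n_hidden_sires: int | None = None
    n_hidden_dams: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "missing_rate", "unrelated_parent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_sires", "n_dams", "n_offspring", "n_snps",
                     "n_duplicate_samples", "n_failing_snps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.failing_mode not in FAILING_MODES:
            raise ValueError(f"failing_mode must be one of {FAILING_MODES}")
        if self.failing_snps is not None:
            for idx, mode in self.failing_snps:
                if not 0 <= idx < self.n_snps:
                    raise ValueError(f"failing SNP index {idx} out of range")
                if mode not in FAILING_MODES:
                    raise ValueError(f"unknown failure mode {mode!r}")
        self.error_model = ErrorModel(self.error_model)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "failing_snps" in raw and raw["failing_snps"] is not None:
            raw["failing_snps"] = [tuple(x) for x in raw["failing_snps"]]
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["error_model"] = self.error_model.value
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``pedigree`` has one row per offspring with its true sire/dam identifiers
    and whether each is among the genotyped candidates.  ``error_mask`` marks
    calls whose observed value differs from the transmitted genotype, aligned
    with the returned matrix.  Sib lists are over offspring pairs sharing
    both (full) or exactly one (half) true parent.
    """

    pedigree: pd.DataFrame
    duplicates: list[tuple[str, str]]
    error_mask: np.ndarray
    full_sibs: list[tuple[str, str]]
    half_sibs: list[tuple[str, str]]
    sire_freqs: np.ndarray
    dam_freqs: np.ndarray
    failing_snp_ids: list[str]


def draw_freqs(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-SNP reference-allele frequencies from a distribution spec.

    Specs: ``{"dist": "beta", "a": .., "b": ..}``, ``{"dist": "uniform",
    "low": .., "high": ..}``, or ``{"dist": "fixed", "values": [..]}``.
    Random draws are clipped away from 0/1 so no locus is monomorphic by
    construction.
    """
    dist = spec.get("dist")
    if dist == "beta":
        p = rng.beta(spec["a"], spec["b"], size=n)
    elif dist == "uniform":
        p = rng.uniform(spec["low"], spec["high"], size=n)
    elif dist == "fixed":
        p = np.broadcast_to(np.asarray(spec["values"], dtype=float), (n,)).copy()
        return p
    else:
        raise ValueError(f"unknown frequency spec {spec!r}")
    return np.clip(p, 1e-3, 1.0 - 1e-3)


def inject_errors(
    calls: np.ndarray,
    error_rate: float,
    error_model: ErrorModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt clean dosages with miscalls; returns (corrupted, changed-mask).

    GENOTYPE_UNIFORM replaces a call, with probability ``error_rate``, by one
    of the other two genotypes with equal probability.  ALLELE_FLIP miscalls
    each of the two alleles independently at rate ``error_rate / 2``.
    """
    error_model = ErrorModel(error_model)
    g = np.asarray(calls, dtype=np.int8)
    if error_rate == 0.0:
        return g.copy(), np.zeros(g.shape, dtype=bool)
    if error_model is ErrorModel.GENOTYPE_UNIFORM:
        hit = rng.random(g.shape) < error_rate
        shift = rng.integers(1, 3, size=g.shape, dtype=np.int8)
        out = np.where(hit, (g + shift) % 3, g).astype(np.int8)
    else:
        flip_ref = rng.binomial(g, error_rate / 2.0).astype(np.int8)
        flip_alt = rng.binomial(2 - g, error_rate / 2.0).astype(np.int8)
        out = (g - flip_ref + flip_alt).astype(np.int8)
    return out, out != g


def _transmit(parent_geno: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per SNP from a parent genotype vector (dosage of REF)."""
    return (rng.random(parent_geno.shape) < parent_geno / 2.0).astype(np.int8)


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, SampleRoles, TruthTable]:
    """Generate one crossbred dataset with full ground truth.

    Sample order: sires, dams, offspring, then duplicate samples.  Hidden
    (ungenotyped) parents are drawn from pools of the same size as the
    candidate pools unless overridden, so half- and full-sib structure also
    exists among offspring of unresolvable parents.
    """
    rng = np.random.default_rng(config.seed)
    n_snps = config.n_snps
    p_s = draw_freqs(config.sire_breed_freqs, n_snps, rng)
    if config.dam_breed_freqs.get("dist") == "shared":
        p_d = p_s  # one breeding pool: dams at the sires' frequencies
    else:
        p_d = draw_freqs(config.dam_breed_freqs, n_snps, rng)

    n_hid_s = config.n_hidden_sires if config.n_hidden_sires is not None else config.n_sires
    n_hid_d = config.n_hidden_dams if config.n_hidden_dams is not None else config.n_dams
    if config.unrelated_parent_fraction > 0 and (n_hid_s == 0 or n_hid_d == 0):
        raise ValueError("hidden parent pools required when "
                         "unrelated_parent_fraction > 0")

    # parents in HWE within their breed pools
    sires = rng.binomial(2, p_s, size=(config.n_sires + n_hid_s, n_snps)).astype(np.int8)
    dams = rng.binomial(2, p_d, size=(config.n_dams + n_hid_d, n_snps)).astype(np.int8)

    sire_ids = [f"sire_{i + 1:03d}" for i in range(config.n_sires)]
    dam_ids = [f"dam_{i + 1:03d}" for i in range(config.n_dams)]
    off_ids = [f"off_{i + 1:03d}" for i in range(config.n_offspring)]
    hid_sire_ids = [f"hidden_sire_{i + 1:03d}" for i in range(n_hid_s)]
    hid_dam_ids = [f"hidden_dam_{i + 1:03d}" for i in range(n_hid_d)]
    all_sire_ids = sire_ids + hid_sire_ids
    all_dam_ids = dam_ids + hid_dam_ids

    # pedigree: each offspring draws its sire/dam from the genotyped pool
    # unless marked unresolvable, then from the hidden pool
    ped_rows = []
    off_calls = np.empty((config.n_offspring, n_snps), dtype=np.int8)
    for k in range(config.n_offspring):
        sire_hidden = rng.random() < config.unrelated_parent_fraction
        dam_hidden = rng.random() < config.unrelated_parent_fraction
        si = (config.n_sires + rng.integers(n_hid_s)) if sire_hidden \
            else rng.integers(config.n_sires)
        di = (config.n_dams + rng.integers(n_hid_d)) if dam_hidden \
            else rng.integers(config.n_dams)
        off_calls[k] = _transmit(sires[si], rng) + _transmit(dams[di], rng)
        ped_rows.append((off_ids[k], all_sire_ids[si], all_dam_ids[di],
                         not sire_hidden, not dam_hidden))
    pedigree = pd.DataFrame(
        ped_rows,
        columns=["offspring_id", "sire_id", "dam_id",
                 "sire_genotyped", "dam_genotyped"],
    )

    # assemble genotyped samples; duplicates copy a mothering dam pre-error
    clean = np.vstack([sires[:config.n_sires], dams[:config.n_dams], off_calls])
    samples = sire_ids + dam_ids + off_ids
    roles = {s: "SIRE" for s in sire_ids}
    roles.update({d: "DAM" for d in dam_ids})
    roles.update({o: "OFFSPRING" for o in off_ids})

    duplicates: list[tuple[str, str]] = []
    mother_ids = [d for d in dam_ids if (pedigree["dam_id"] == d).any()]
    dup_pool = mother_ids + [d for d in dam_ids if d not in mother_ids]
    for k in range(config.n_duplicate_samples):
        orig = dup_pool[k % len(dup_pool)] if dup_pool else None
        if orig is None:
            break
        dup_id = f"{orig}_dup{k + 1}"
        clean = np.vstack([clean, clean[samples.index(orig)][None, :]])
        samples.append(dup_id)
        roles[dup_id] = "DAM"
        duplicates.append((dup_id, orig))

    # systematically failing SNPs corrupt the clean matrix per sample
    failing = config.failing_snps
    if failing is None and config.n_failing_snps > 0:
        idx = rng.choice(n_snps, size=min(config.n_failing_snps, n_snps),
                         replace=False)
        failing = [(int(j), config.failing_mode) for j in sorted(idx)]
    failing = failing or []
    n_samp = clean.shape[0]
    for j, mode in failing:
        if mode == "force_hom":
            clean[:, j] = 2 * rng.integers(0, 2, size=n_samp, dtype=np.int8)
        elif mode == "random_call":
            clean[:, j] = rng.integers(0, 3, size=n_samp, dtype=np.int8)
        else:  # shuffle: genotypes swapped among samples at this SNP
            clean[:, j] = clean[rng.permutation(n_samp), j]

    observed, error_mask = inject_errors(
        clean, config.error_rate, config.error_model, rng)
    if config.missing_rate > 0:
        miss = rng.random(observed.shape) < config.missing_rate
        observed = observed.copy()
        observed[miss] = MISSING

    snps = pd.DataFrame({
        "snp_id": [f"snp_{j + 1:06d}" for j in range(n_snps)],
        "chrom": [str(j % 18 + 1) for j in range(n_snps)],
        "pos": [j // 18 * 1000 + 1 for j in range(n_snps)],
    })
    g = GenotypeMatrix(samples, snps, observed)

    full_sibs, half_sibs = _sib_pairs(pedigree)
    truth = TruthTable(
        pedigree=pedigree,
        duplicates=duplicates,
        error_mask=error_mask,
        full_sibs=full_sibs,
        half_sibs=half_sibs,
        sire_freqs=p_s,
        dam_freqs=p_d,
        failing_snp_ids=[snps["snp_id"].iloc[j] for j, _ in failing],
    )
    return g, SampleRoles(roles), truth


def _sib_pairs(pedigree: pd.DataFrame) -> tuple[list, list]:
    full, half = [], []
    rows = list(pedigree.itertuples(index=False))
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            shared = (rows[a].sire_id == rows[b].sire_id) + \
                     (rows[a].dam_id == rows[b].dam_id)
            if shared == 2:
                full.append((rows[a].offspring_id, rows[b].offspring_id))
            elif shared == 1:
                half.append((rows[a].offspring_id, rows[b].offspring_id))
    return full, half


def tau_histogram(
    rejections: pd.DataFrame, bins: int = 50
) -> pd.DataFrame:
    """Histogram of per-pair rejection rates, one set of counts per group.

    Shared bin edges over [0, max(tau)] so group distributions are directly
    comparable (the crossbred sire-dam group sits far to the right of every
    other group).  Returns a long table: group, bin_left, bin_right, count.
    """
    taus = rejections["tau"].to_numpy(dtype=float)
    finite = taus[np.isfinite(taus)]
    top = float(finite.max()) if finite.size else 1.0
    edges = np.linspace(0.0, top if top > 0 else 1.0, bins + 1)
    out = []
    for grp, sub in rejections.groupby("group", sort=True):
        counts, _ = np.histogram(sub["tau"].dropna(), bins=edges)
        for k in range(bins):
            out.append((grp, edges[k], edges[k + 1], int(counts[k])))
    return pd.DataFrame(out, columns=["group", "bin_left", "bin_right", "count"])
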