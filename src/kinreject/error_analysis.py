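"""Genotyping-error estimation and Mendelian-inconsistency SNP QC.

The fitted error-component rate tau_g is only a lower bound on the
per-genotype miscall rate e: a miscall is detected solely when it turns a
compatible parent-offspring genotype pair into opposing homozygotes, which
requires the *other* member of the pair to be homozygous (or, under
allele-level errors, the miscalled individual to be heterozygous next to a
homozygous partner).  The chance of that depends on the allele frequency, so
the observable rejection rate at a SNP with reference-allele frequency p is,
to first order in e,

    tau(p) = e * c(p)

where c(p) is the detection factor of the chosen error model:

* ``GENOTYPE_UNIFORM`` (default): with probability e a call is replaced by
  one of the other two genotypes with equal probability.  A single miscall
  in the pair creates opposing homozygotes whenever the unmiscalled partner
  is homozygous, giving c(p) = p^2 + q^2 (q = 1 - p).  As p -> 0 or 1,
  c -> 1 and the rejection rate approaches the raw error rate.
* ``ALLELE_FLIP``: each allele is miscalled independently at rate e/2, so
  single-allele events move calls between adjacent genotype classes and only
  a heterozygote can flip into an opposing homozygote: c(p) = p*q, which
  vanishes at extreme frequencies (low-MAF SNPs almost never reject).

When the two parental pools differ in frequency (crossbred designs) the
factors generalize to c = (p^2 + q^2 + p*p_o + q*q_o) / 2 and
c = (p*q_o + q*p_o) / 2 respectively, with p the pool frequency of the
genotyped parent and p_o that of the other (possibly ungenotyped) parent.
Both closed forms are validated against exhaustive enumeration in the test
suite.

The adjusted genome-wide error estimate is e = tau_g / mean_snps[c(p)].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


class ErrorModel(str, Enum):
    """Per-call miscall models used for injection and for the c(p) adjustment."""

    GENOTYPE_UNIFORM = "genotype_uniform"
    ALLELE_FLIP = "allele_flip"


class DegenerateLocusError(ValueError):
    """Allele frequency 0 or 1: the locus is monomorphic."""


@dataclass
class ErrorEstimate:
    """Genotyping-error estimate derived from verified parent-offspring pairs."""

    tau_g_lower_bound: float
    adjusted_error: float
    detection_factor: float
    error_model: ErrorModel

    def to_dict(self) -> dict:
        return {
            "tau_g_lower_bound": self.tau_g_lower_bound,
            "adjusted_error": self.adjusted_error,
            "detection_factor": self.detection_factor,
            "error_model": self.error_model.value,
        }


def rejection_detection_prob(
    p: float,
    error_model: ErrorModel = ErrorModel.GENOTYPE_UNIFORM,
    p_other: float | None = None,
) -> float:
    """Detection factor c(p): P(one miscall produces opposing homozygotes).

    ``p`` is the reference-allele frequency of the genotyped parent's pool
    (HWE assumed); ``p_other`` that of the other parent's pool (defaults to
    ``p``).  Symmetric in p <-> 1-p when the pools coincide, so a MAF may be
    passed directly.
    """
    error_model = ErrorModel(error_model)
    if not 0.0 < p < 1.0:
        raise DegenerateLocusError(f"allele frequency {p} is degenerate")
    po = p if p_other is None else p_other
    if not 0.0 < po < 1.0:
        raise DegenerateLocusError(f"allele frequency {po} is degenerate")
    q, qo = 1.0 - p, 1.0 - po
    if error_model is ErrorModel.GENOTYPE_UNIFORM:
        return 0.5 * (p * p + q * q + p * po + q * qo)
    return 0.5 * (p * qo + q * po)


def detection_factors(
    freqs: np.ndarray,
    error_model: ErrorModel = ErrorModel.GENOTYPE_UNIFORM,
    freqs_other: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized c(p) over an array of frequencies (NaN-propagating)."""
    error_model = ErrorModel(error_model)
    p = np.asarray(freqs, dtype=float)
    po = p if freqs_other is None else np.asarray(freqs_other, dtype=float)
    q, qo = 1.0 - p, 1.0 - po
    if error_model is ErrorModel.GENOTYPE_UNIFORM:
        return 0.5 * (p * p + q * q + p * po + q * qo)
    return 0.5 * (p * qo + q * po)


def snp_rejection_counts(
    g: GenotypeMatrix,
    verified_pairs: Sequence[tuple[str, str]],
    chunk_size: int = 512,
) -> pd.DataFrame:
    """Per-SNP count of verified parent-offspring pairs showing opposing homozygotes.

    Returns the SNP map annotated with ``maf`` and ``n_rejections``.  Summing
    ``n_rejections`` over SNPs equals summing delta over the verified pairs
    (every rejection is one pair-SNP event).
    """
    from .genotype_io import snp_summaries

    ia = np.asarray([g.sample_index(a) for a, _ in verified_pairs], dtype=int)
    ib = np.asarray([g.sample_index(b) for _, b in verified_pairs], dtype=int)
    counts = np.zeros(g.n_snps, dtype=np.int64)
    for start in range(0, len(ia), chunk_size):
        sl = slice(start, start + chunk_size)
        a = g.calls[ia[sl]]
        b = g.calls[ib[sl]]
        opp = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
        counts += opp.sum(axis=0)
    out = snp_summaries(g)[["snp_id", "chrom", "pos", "maf"]].copy()
    out["n_rejections"] = counts
    return out


def flag_failing_snps(profiles: pd.DataFrame, threshold: int = 5) -> pd.DataFrame:
    """Mark SNPs rejecting ``threshold`` or more verified pairs as failing.

    The default of five recurrent Mendelian inconsistencies separates
    isolated miscalls from systematically misbehaving assays (mismapping,
    structural variation, cluster-calling failure).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out = profiles.copy()
    out["failing"] = out["n_rejections"] >= threshold
    return out


def rejection_histogram(profiles: pd.DataFrame) -> pd.DataFrame:
    """Histogram of per-SNP rejection counts (rows: n_rejections, n_snps)."""
    counts = profiles["n_rejections"].value_counts().sort_index()
    return pd.DataFrame({"n_rejections": counts.index, "n_snps": counts.values})


def adjusted_error_rate(
    tau_g: float,
    summaries: pd.DataFrame,
    error_model: ErrorModel = ErrorModel.GENOTYPE_UNIFORM,
) -> ErrorEstimate:
    """Convert the rejection-rate lower bound tau_g into a per-genotype error rate.

    e = tau_g / mean[c(p)] with the mean taken over SNPs with a defined,
    polymorphic MAF (``summaries`` as produced by
    :func:`kinreject.genotype_io.snp_summaries`).  Because c(p) <= 1 the
    adjusted rate is never below tau_g.
    """
    if tau_g < 0:
        raise ValueError("tau_g must be non-negative")
    error_model = ErrorModel(error_model)
    maf = summaries["maf"].to_numpy(dtype=float)
    maf = maf[np.isfinite(maf) & (maf > 0.0)]
    if maf.size == 0:
        raise ValueError("no SNP with a defined polymorphic MAF")
    factor = float(detection_factors(maf, error_model).mean())
    if factor <= 0.0:
        raise ValueError("mean detection factor is zero; adjustment undefined")
    return ErrorEstimate(
        tau_g_lower_bound=float(tau_g),
        adjusted_error=float(tau_g) / factor,
        detection_factor=factor,
        error_model=error_model,
    )


def maf_stratified_report(
    profiles: pd.DataFrame,
    summaries: pd.DataFrame,
    maf_cut: float = 0.05,
) -> pd.DataFrame:
    """Proportion of low-MAF SNPs overall vs among rejecting SNPs.

    A rejecting SNP is one with at least one rejection of a verified pair.
    Rows: ``all_snps`` and ``rejecting_snps`` with counts below the MAF cut,
    totals, and the proportion (NaN when the stratum is empty).
    """
    maf_all = summaries["maf"].to_numpy(dtype=float)
    defined = np.isfinite(maf_all)
    n_all = int(defined.sum())
    n_low_all = int((maf_all[defined] < maf_cut).sum())

    rejecting = profiles[profiles["n_rejections"] > 0]
    maf_rej = rejecting["maf"].to_numpy(dtype=float)
    rej_defined = np.isfinite(maf_rej)
    n_rej = int(rej_defined.sum())
    n_low_rej = int((maf_rej[rej_defined] < maf_cut).sum())

    def prop(low: int, total: int) -> float:
        return low / total if total else float("nan")

    return pd.DataFrame({
        "stratum": ["all_snps", "rejecting_snps"],
        "n_low_maf": [n_low_all, n_low_rej],
        "n_total": [n_all, n_rej],
        "proportion": [prop(n_low_all, n_all), prop(n_low_rej, n_rej)],
    })
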