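"""Opposing-homozygote exclusion statistics for all sample pairs.

Under strict Mendelian inheritance a parent and its offspring cannot be
homozygous for alternative alleles at any locus, so for a true
parent-offspring pair the count of opposing-homozygote SNPs (delta) is zero
absent genotyping error.  The rejection rate tau = delta / n_eff, where
n_eff counts SNPs at which both genotypes were called, is the per-pair
statistic everything downstream is built on.  Full sibs can show opposing
homozygotes: at a locus where both parents are heterozygous the probability
is exactly 1/8.

The pairwise computation is a handful of dense matrix products over
indicator matrices, not a per-pair loop: 300 samples x 50k SNPs takes
seconds on one CPU.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genotype_io import MISSING, GenotypeMatrix, SampleRoles

#: Relationship groups induced by the {SIRE, DAM, OFFSPRING} roles.
GROUPS = ("DAM_OFF", "SIRE_OFF", "OFF_OFF", "DAM_DAM", "SIRE_SIRE", "SIRE_DAM")

_GROUP_BY_ROLES = {
    frozenset(("DAM", "OFFSPRING")): "DAM_OFF",
    frozenset(("SIRE", "OFFSPRING")): "SIRE_OFF",
    frozenset(("OFFSPRING",)): "OFF_OFF",
    frozenset(("DAM",)): "DAM_DAM",
    frozenset(("SIRE",)): "SIRE_SIRE",
    frozenset(("SIRE", "DAM")): "SIRE_DAM",
}

PAIR_COLUMNS = ["sample_i", "sample_j", "group", "delta", "n_eff", "tau"]


def pair_count(ni: int) -> int:
    """Number of unordered pairs among ``ni`` individuals: ni*(ni-1)/2."""
    if ni < 2:
        raise ValueError("need at least 2 individuals")
    return ni * (ni - 1) // 2


def group_of(role_i: str, role_j: str) -> str:
    """Relationship group of a pair given its two roles."""
    return _GROUP_BY_ROLES[frozenset((role_i, role_j))]


def _pairwise_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense opposing-homozygote and both-called counts for all pairs.

    Returns (delta, n_eff) as n x n symmetric integer matrices.
    """
    hom_ref = (calls == 2).astype(np.float64)
    hom_alt = (calls == 0).astype(np.float64)
    called = (calls != MISSING).astype(np.float64)
    delta = hom_ref @ hom_alt.T
    delta = delta + delta.T
    n_eff = called @ called.T
    return delta.astype(np.int64), n_eff.astype(np.int64)


def pairwise_rejections(g: GenotypeMatrix, roles: SampleRoles) -> pd.DataFrame:
    """Rejection statistics for every unordered sample pair.

    Returns a DataFrame with one row per pair (i < j in sample order) and
    columns ``sample_i, sample_j, group, delta, n_eff, tau`` where ``tau`` is
    ``delta / n_eff`` (NaN when no SNP is jointly called).
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    roles.validate_against(g)
    delta, n_eff = _pairwise_counts(g.calls)
    iu, ju = np.triu_indices(g.n_samples, k=1)
    d = delta[iu, ju]
    n = n_eff[iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.where(n > 0, d / n, np.nan)
    sample_arr = np.asarray(g.samples, dtype=object)
    role_list = [roles[s] for s in g.samples]
    groups = [group_of(role_list[i], role_list[j]) for i, j in zip(iu, ju)]
    return pd.DataFrame({
        "sample_i": sample_arr[iu],
        "sample_j": sample_arr[ju],
        "group": groups,
        "delta": d,
        "n_eff": n,
        "tau": tau,
    })


def binomial_rejection_prob(
    tau: float, n_snp: int, delta: int, log: bool = False
) -> float:
    """Binomial probability of observing ``delta`` rejections in ``n_snp`` SNPs.

    C(n_snp, delta) * tau^delta * (1-tau)^(n_snp-delta), computed in log
    space; set ``log=True`` for the log probability.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must be in [0, 1]")
    if not 0 <= delta <= n_snp:
        raise ValueError("delta must be in [0, n_snp]")
    lp = binom.logpmf(delta, n_snp, tau)
    return float(lp) if log else float(np.exp(lp))


def detect_duplicates(
    g: GenotypeMatrix, concordance_threshold: float = 0.99
) -> pd.DataFrame:
    """Flag sample pairs that are the same individual.

    Concordance is the fraction of jointly called SNPs with identical
    genotypes.  Pairs at or above the threshold are returned as a DataFrame
    (``sample_i, sample_j, concordance, n_eff``), ordered by sample order.
    Parent-offspring pairs sit far below any sensible threshold (~0.6-0.8
    concordance), duplicates at ~(1-e)^2 for per-call error rate e.
    """
    if not 0.9 < concordance_threshold <= 1.0:
        raise ValueError("concordance_threshold must be in (0.9, 1]")
    calls = g.calls
    equal = np.zeros((g.n_samples, g.n_samples))
    for val in (0, 1, 2):
        ind = (calls == val).astype(np.float64)
        equal += ind @ ind.T
    called = (calls != MISSING).astype(np.float64)
    n_eff = called @ called.T
    iu, ju = np.triu_indices(g.n_samples, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(n_eff[iu, ju] > 0, equal[iu, ju] / n_eff[iu, ju], np.nan)
    keep = conc >= concordance_threshold
    sample_arr = np.asarray(g.samples, dtype=object)
    return pd.DataFrame({
        "sample_i": sample_arr[iu[keep]],
        "sample_j": sample_arr[ju[keep]],
        "concordance": conc[keep],
        "n_eff": n_eff[iu, ju][keep].astype(np.int64),
    })


# ---------------------------------------------------------------------------
# Full-sib opposing-homozygote probability
# ---------------------------------------------------------------------------

def fullsib_opposing_prob() -> Fraction:
    """Exact P(full sibs opposing-homozygous | both parents heterozygous).

    Enumerates the four transmissions to each sib at a het x het locus; the
    value is 1/8 (each sib homozygous with probability 1/4, opposite
    homozygotes in two of the sixteen joint outcomes... counted exactly).
    """
    total = Fraction(0)
    # each sib receives one allele from each het parent, uniformly
    for a1, b1, a2, b2 in product((0, 1), repeat=4):
        g1, g2 = a1 + b1, a2 + b2
        if {g1, g2} == {0, 2}:
            total += Fraction(1, 16)
    return total


def simulate_fullsib_opposing_rate(
    n_loci: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo estimate of the full-sib opposing probability.

    Simulates ``n_loci`` independent loci with both parents heterozygous and
    two offspring per locus.  Returns (estimate, standard error).
    """
    g1 = rng.integers(0, 2, n_loci) + rng.integers(0, 2, n_loci)
    g2 = rng.integers(0, 2, n_loci) + rng.integers(0, 2, n_loci)
    opp = ((g1 == 0) & (g2 == 2)) | ((g1 == 2) & (g2 == 0))
    p_hat = float(opp.mean())
    se = float(np.sqrt(p_hat * (1 - p_hat) / n_loci))
    return p_hat, se
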