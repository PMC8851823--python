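"""SNP-count requirements for separating the two rejection-rate components.

Deciding whether one pair's rate belongs to the error component (rate p0 =
tau_g) or the rejection component (p1 = tau_r) is a one-sample proportion
test repeated over every pair in the group, so the significance level is
Bonferroni-adjusted by the number of pairs, ni*(ni-1)/2.  The required SNP
count comes from the normal approximation to the binomial:

    n = ceil( [ z_{1-a/2} sqrt(p0 q0) + z_{power} sqrt(p1 q1) ]^2
              / (p1 - p0)^2 )

with a the adjusted level.  The critical value is two-sided by default
(a one-sided variant is available via ``two_sided=False``).  No continuity
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .exclusion import pair_count


@dataclass
class PowerDesign:
    """Inputs and result of a required-SNP-count computation."""

    p0: float
    p1: float
    alpha_global: float
    power: float
    n_individuals: int
    n_tests: int
    alpha_adjusted: float
    required_snps: int
    two_sided: bool = True

    def to_dict(self) -> dict:
        return {
            "p0": self.p0, "p1": self.p1,
            "alpha_global": self.alpha_global, "power": self.power,
            "n_individuals": self.n_individuals, "n_tests": self.n_tests,
            "alpha_adjusted": self.alpha_adjusted,
            "required_snps": self.required_snps,
            "two_sided": self.two_sided,
        }


def _validate(p0: float, p1: float, alpha_global: float, power: float) -> None:
    if not 0.0 < p0 < p1 < 1.0:
        raise ValueError("need 0 < p0 < p1 < 1")
    if not 0.0 < alpha_global < 1.0:
        raise ValueError("alpha_global must be in (0, 1)")
    if not 0.5 < power < 1.0:
        raise ValueError("power must be in (0.5, 1)")


def required_snps(
    p0: float,
    p1: float,
    alpha_global: float,
    power: float,
    n_individuals: int,
    two_sided: bool = True,
) -> PowerDesign:
    """Number of SNPs needed to tell rate p0 from p1 across all pairwise tests.

    ``alpha_global`` is divided by the pair count of ``n_individuals``
    (Bonferroni) before computing the critical value.
    """
    _validate(p0, p1, alpha_global, power)
    n_tests = pair_count(n_individuals)
    alpha_adj = alpha_global / n_tests
    z_alpha = norm.ppf(1.0 - (alpha_adj / 2.0 if two_sided else alpha_adj))
    z_beta = norm.ppf(power)
    num = z_alpha * math.sqrt(p0 * (1.0 - p0)) + z_beta * math.sqrt(p1 * (1.0 - p1))
    n = math.ceil(num * num / (p1 - p0) ** 2)
    return PowerDesign(
        p0=p0, p1=p1, alpha_global=alpha_global, power=power,
        n_individuals=n_individuals, n_tests=n_tests,
        alpha_adjusted=alpha_adj, required_snps=int(n), two_sided=two_sided,
    )


def achieved_power(
    n_snps: int,
    p0: float,
    p1: float,
    alpha_adjusted: float,
    two_sided: bool = True,
) -> float:
    """Normal-approximation power of the test at a fixed SNP count.

    Inverse of :func:`required_snps` (which already folds the Bonferroni
    adjustment into ``alpha_adjusted``); monotone increasing in ``n_snps``.
    """
    if not 0.0 < p0 < p1 < 1.0:
        raise ValueError("need 0 < p0 < p1 < 1")
    if not 0.0 < alpha_adjusted < 1.0:
        raise ValueError("alpha_adjusted must be in (0, 1)")
    if n_snps < 1:
        raise ValueError("n_snps must be positive")
    z_alpha = norm.ppf(1.0 - (alpha_adjusted / 2.0 if two_sided else alpha_adjusted))
    z = ((p1 - p0) * math.sqrt(n_snps) - z_alpha * math.sqrt(p0 * (1.0 - p0))) \
        / math.sqrt(p1 * (1.0 - p1))
    return float(norm.cdf(z))
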