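"""Two-component binomial mixture fitted by Expectation-Maximization.

Within one relationship group, each pair's opposing-homozygote count delta_i
is modelled as Binomial(n_i, tau_g) with probability gamma (true first-degree
pairs, rejections caused only by genotyping error) or Binomial(n_i, tau_r)
with probability 1 - gamma (pairs that genuinely are not first-degree).  The
likelihood of pair i is

    L_i(gamma, tau_g, tau_r) = gamma * L_i(tau_g) + (1 - gamma) * L_i(tau_r)

with L_i(tau) the binomial pmf at delta_i.  Because binomial probabilities
underflow at hundreds of thousands of SNPs, the E-step uses the stabilized
log-difference form

    r_i = 1 / (1 + exp(ln L_i(tau_r) - ln L_i(tau_g)))

and never exponentiates a raw likelihood.  By default the responsibility
ratio carries no gamma prior weight (set ``use_gamma_weights=True`` for the
standard gamma-weighted posterior; with well-separated components the two
give identical assignments).  The M-step is the delta-weighted estimator

    tau_g' = sum_i r_i * delta_i * (delta_i / n_i) / sum_i r_i * delta_i

(and mirrored for tau_r with weights (1 - r_i) * delta_i); pairs with
delta_i = 0 therefore carry no weight and tau_g is driven by pairs with at
least one rejection.  gamma is re-estimated as the mean responsibility.
A pair is assigned as a true first-degree relationship when its
responsibility exceeds 0.5 (ties conservatively not assigned).

The likelihood uses each pair's own n_eff rather than one global SNP count,
which is identical when there is no missingness and less biased otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from scipy.stats import binom

logger = logging.getLogger(__name__)


class SingleModeError(ValueError):
    """All observed rejection rates identical; no two-component structure."""


@dataclass
class MixtureFit:
    """Result of an EM fit.

    ``assignments[i]`` is True when pair i is assigned to the
    genotyping-error component, i.e. accepted as a true first-degree
    relationship.  ``trace`` has one row per iteration with the parameter
    values and the observed-data log-likelihood after that iteration.
    ``collapsed`` marks degenerate fits where one component took all the
    weight (e.g. every delta zero).
    """

    tau_g: float
    tau_r: float
    gamma: float
    responsibilities: np.ndarray
    assignments: np.ndarray
    trace: pd.DataFrame
    converged: bool
    n_iter: int
    log_likelihood: float
    collapsed: bool = False
    init: tuple[float, float] = field(default=(np.nan, np.nan))


def pair_log_likelihood(
    delta: np.ndarray | int, n: np.ndarray | int, tau: float
) -> np.ndarray | float:
    """Log binomial pmf ln C(n, delta) + delta ln tau + (n-delta) ln(1-tau).

    Boundary rates are handled exactly: tau = 0 gives 0 when delta = 0 and
    -inf otherwise (symmetrically for tau = 1).
    """
    scalar = np.isscalar(delta) and np.isscalar(n)
    delta = np.asarray(delta)
    n = np.asarray(n)
    if tau <= 0.0:
        out = np.where(delta == 0, 0.0, -np.inf)
    elif tau >= 1.0:
        out = np.where(delta == n, 0.0, -np.inf)
    else:
        out = binom.logpmf(delta, n, tau)
    return float(out) if scalar else out


def e_step(
    delta: np.ndarray,
    n: np.ndarray,
    tau_g: float,
    tau_r: float,
    gamma: float | None = None,
) -> np.ndarray:
    """Responsibilities of the genotyping-error component for each pair.

    Computed as 1 / (1 + exp(lnL_i(tau_r) - lnL_i(tau_g))); pass ``gamma``
    to add the prior log-odds ln(gamma / (1-gamma)) to the ratio (the
    gamma-weighted posterior variant).
    """
    if tau_g == tau_r:
        raise ValueError("tau_g and tau_r must differ")
    ll_g = pair_log_likelihood(delta, n, tau_g)
    ll_r = pair_log_likelihood(delta, n, tau_r)
    log_odds = ll_g - ll_r
    if gamma is not None:
        if not 0.0 < gamma < 1.0:
            raise ValueError("gamma must be in (0, 1) for prior weighting")
        log_odds = log_odds + np.log(gamma) - np.log1p(-gamma)
    # handle -inf minus -inf from boundary taus: equal evidence -> 0.5
    log_odds = np.where(np.isnan(log_odds), 0.0, log_odds)
    return expit(log_odds)


def m_step(
    delta: np.ndarray, n: np.ndarray, responsibilities: np.ndarray
) -> tuple[float, float, float]:
    """Update (tau_g, tau_r, gamma) from responsibilities.

    Rates are delta-weighted means of delta_i/n_i (weight = responsibility x
    delta_i for the error component, complement for the rejection
    component); a component with zero total weight keeps collapsing to the
    other's rate and is reported by the caller.  gamma is the mean
    responsibility.
    """
    r = np.asarray(responsibilities, dtype=float)
    taus = delta / n
    w_g = r * delta
    w_r = (1.0 - r) * delta
    sum_g, sum_r = w_g.sum(), w_r.sum()
    pooled = float(taus.mean())
    tau_g = float((w_g * taus).sum() / sum_g) if sum_g > 0 else pooled
    tau_r = float((w_r * taus).sum() / sum_r) if sum_r > 0 else pooled
    gamma = float(r.mean())
    return tau_g, tau_r, gamma


def observed_log_likelihood(
    delta: np.ndarray, n: np.ndarray, tau_g: float, tau_r: float, gamma: float
) -> float:
    """Joint log-likelihood of all pairs under the two-component mixture."""
    ll_g = pair_log_likelihood(delta, n, tau_g)
    ll_r = pair_log_likelihood(delta, n, tau_r)
    eps = np.finfo(float).tiny
    comp = np.stack([
        np.log(max(gamma, eps)) + ll_g,
        np.log(max(1.0 - gamma, eps)) + ll_r,
    ])
    return float(logsumexp(comp, axis=0).sum())


def default_init(delta: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Data-driven starting rates near the two modes of the tau distribution.

    Uses the 5th and 60th percentiles of the per-pair rates; if those
    coincide, falls back to the means of the two sides of the largest gap in
    the sorted rates.  Raises :class:`SingleModeError` when every rate is
    identical.
    """
    taus = np.sort(np.asarray(delta) / np.asarray(n))
    if taus[0] == taus[-1]:
        raise SingleModeError("all per-pair rates identical")
    lo, hi = np.percentile(taus, [5.0, 60.0])
    if lo == hi:
        lo, hi = _largest_gap_split(taus)
    return float(lo), float(hi)


def _largest_gap_split(sorted_taus: np.ndarray) -> tuple[float, float]:
    gaps = np.diff(sorted_taus)
    k = int(np.argmax(gaps))
    return float(sorted_taus[: k + 1].mean()), float(sorted_taus[k + 1:].mean())


def _candidate_inits(delta: np.ndarray, n: np.ndarray) -> list[tuple[float, float]]:
    """Deterministic multi-start candidates (guards against bad starts)."""
    taus = np.sort(delta / n)
    cands = [default_init(delta, n)]
    q25, q75 = np.percentile(taus, [25.0, 75.0])
    if q25 < q75:
        cands.append((float(q25), float(q75)))
    cands.append(_largest_gap_split(taus))
    seen: list[tuple[float, float]] = []
    for c in cands:
        if c[0] != c[1] and c not in seen:
            seen.append(c)
    return seen


def _em_once(
    delta: np.ndarray,
    n: np.ndarray,
    init: tuple[float, float],
    max_iter: int,
    tol: float,
    use_gamma_weights: bool,
    assign_threshold: float,
) -> MixtureFit:
    tau_g, tau_r = sorted(init)
    gamma = 0.5
    rows = []
    converged = False
    resp = np.full(len(delta), 0.5)
    for it in range(1, max_iter + 1):
        resp = e_step(delta, n, tau_g, tau_r,
                      gamma if use_gamma_weights else None)
        new_g, new_r, new_gamma = m_step(delta, n, resp)
        if new_g > new_r:  # keep components ordered; swap labels
            new_g, new_r = new_r, new_g
            resp = 1.0 - resp
            new_gamma = 1.0 - new_gamma
        rel = max(
            _rel_change(tau_g, new_g),
            _rel_change(tau_r, new_r),
            _rel_change(gamma, new_gamma),
        )
        tau_g, tau_r, gamma = new_g, new_r, new_gamma
        ll = observed_log_likelihood(delta, n, tau_g, tau_r, gamma)
        rows.append((it, tau_g, tau_r, gamma, ll))
        if rel < tol or tau_g == tau_r:
            converged = rel < tol
            break
    trace = pd.DataFrame(
        rows, columns=["iteration", "tau_g", "tau_r", "gamma", "log_likelihood"]
    )
    if tau_g == tau_r:
        collapsed = True
    else:
        resp = e_step(delta, n, tau_g, tau_r,
                      gamma if use_gamma_weights else None)
        collapsed = bool(resp.min() > 0.5 or resp.max() < 0.5)
    return MixtureFit(
        tau_g=tau_g, tau_r=tau_r, gamma=gamma,
        responsibilities=resp,
        assignments=resp > assign_threshold,
        trace=trace, converged=converged, n_iter=len(trace),
        log_likelihood=float(trace["log_likelihood"].iloc[-1]),
        collapsed=collapsed, init=tuple(sorted(init)),
    )


def _rel_change(old: float, new: float) -> float:
    if old == new:
        return 0.0
    denom = max(abs(old), np.finfo(float).tiny)
    return abs(new - old) / denom


def fit_mixture(
    delta: np.ndarray,
    n_eff: np.ndarray,
    init: tuple[float, float] | None = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
    use_gamma_weights: bool = False,
    assign_threshold: float = 0.5,
    multi_start: bool = True,
) -> MixtureFit:
    """Fit the two-component binomial mixture to per-pair (delta, n_eff).

    With explicit ``init`` the fit starts there only; otherwise several
    deterministic data-driven starts are tried (5/60 percentiles, 25/75,
    largest-gap split) and the fit with the highest final observed-data
    log-likelihood wins.  With components separated as in real array data
    convergence takes two to three iterations.

    Degenerate inputs (every pair at the same rate, e.g. all delta = 0)
    yield a collapsed single-component fit with gamma = 1 and every pair
    assigned, flagged via ``collapsed=True``.
    """
    delta = np.asarray(delta, dtype=np.float64)
    n_eff = np.asarray(n_eff, dtype=np.float64)
    if len(delta) < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(n_eff <= 0):
        raise ValueError("n_eff must be positive for every pair")

    taus = delta / n_eff
    if taus.min() == taus.max():
        rate = float(taus[0])
        trace = pd.DataFrame(
            [(1, rate, rate, 1.0, observed_log_likelihood(delta, n_eff, rate, rate, 1.0))],
            columns=["iteration", "tau_g", "tau_r", "gamma", "log_likelihood"],
        )
        logger.warning("single-mode data: returning collapsed fit")
        return MixtureFit(
            tau_g=rate, tau_r=rate, gamma=1.0,
            responsibilities=np.ones(len(delta)),
            assignments=np.ones(len(delta), dtype=bool),
            trace=trace, converged=True, n_iter=1,
            log_likelihood=float(trace["log_likelihood"].iloc[0]),
            collapsed=True, init=(rate, rate),
        )

    if init is not None:
        if init[0] == init[1]:
            raise ValueError("initial rates must be distinct")
        starts = [init]
    elif multi_start:
        starts = _candidate_inits(delta, n_eff)
    else:
        starts = [default_init(delta, n_eff)]

    fits = [
        _em_once(delta, n_eff, s, max_iter, tol, use_gamma_weights,
                 assign_threshold)
        for s in starts
    ]
    best = max(fits, key=lambda f: f.log_likelihood)
    if not best.converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    if best.collapsed:
        logger.warning("mixture collapsed to a single component")
    return best


def fit_group(
    pairs: pd.DataFrame, group: str | None = None, **kwargs
) -> tuple[pd.DataFrame, MixtureFit]:
    """Fit one relationship group of a pairwise-rejection table.

    Convenience wrapper: filters ``pairs`` to ``group`` (if given), fits the
    mixture on its (delta, n_eff) columns, and returns the subset annotated
    with ``responsibility`` and ``assigned`` columns alongside the fit.
    """
    sub = pairs if group is None else pairs[pairs["group"] == group]
    sub = sub.reset_index(drop=True)
    fit = fit_mixture(sub["delta"].to_numpy(), sub["n_eff"].to_numpy(), **kwargs)
    out = sub.copy()
    out["responsibility"] = fit.responsibilities
    out["assigned"] = fit.assignments
    return out, fit
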