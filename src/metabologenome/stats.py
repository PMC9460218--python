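"""Paired-outcome statistics for crossover trial analysis.

Thin, validated wrappers around scipy/statsmodels routines plus a paired
Hedge's g with a noncentral-t confidence interval. All tests are two-sided.

Conventions
-----------
* ``paired_t`` / ``hedges_g_paired`` operate on the per-subject differences
  ``x - y`` and refuse degenerate (zero-variance) inputs rather than
  returning infinite statistics.
* ``wilcoxon_signed_rank`` drops zero differences, uses the exact null
  distribution for n <= 25 without ties in |differences|, and otherwise a
  normal approximation with tie and continuity corrections.
* ``spearman_test`` deletes pairs with missing values, computes rho on
  mid-ranks, and derives p from t = rho * sqrt((n-2)/(1-rho^2)); for
  |rho| = 1 the p-value is floored at the two-sided permutation bound 2/n!.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateDataError",
    "PairedEffect",
    "paired_t",
    "hedges_g_paired",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "spearman_test",
]


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the given data
    (zero-variance differences, constant vectors, empty input)."""


@dataclass(frozen=True)
class PairedEffect:
    """Paired t-test plus standardized effect size for one outcome.

    Attributes
    ----------
    n : number of pairs
    mean_diff : mean of x - y, in outcome units
    t, p : paired t statistic and two-sided p-value (df = n - 1)
    g : paired Hedge's g (bias-corrected standardized mean difference)
    g_ci_low, g_ci_high : confidence interval for g
    ci_level : nominal coverage of the interval
    """

    n: int
    mean_diff: float
    t: float
    p: float
    g: float
    g_ci_low: float
    g_ci_high: float
    ci_level: float

    def __post_init__(self) -> None:
        if not (self.g_ci_low <= self.g <= self.g_ci_high):
            raise ValueError("effect-size CI must bracket the point estimate")


def _paired_diffs(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise DegenerateDataError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x - y


def paired_t(x, y) -> tuple[float, float, int]:
    """Two-sided paired t-test on the differences x - y.

    Returns ``(t, p, df)`` with df = n - 1. Raises
    :class:`DegenerateDataError` if the differences have zero variance.
    """
    d = _paired_diffs(x, y)
    if np.std(d, ddof=1) == 0:
        raise DegenerateDataError("differences have zero variance")
    res = sps.ttest_rel(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue), d.size - 1


def _ncp_confint(t_obs: float, df: int, ci_level: float) -> tuple[float, float]:
    """Confidence interval for the noncentrality parameter of a t statistic.

    Inverts the noncentral-t CDF: the lower bound L solves
    ``P(T >= t_obs | ncp=L) = alpha/2`` and the upper bound U solves
    ``P(T <= t_obs | ncp=U) = alpha/2``.
    """
    alpha = 1.0 - ci_level

    def sf(ncp: float) -> float:
        v = sps.nct.sf(t_obs, df, ncp)
        if np.isnan(v):  # scipy underflows at extreme noncentrality
            return 1.0 if ncp > t_obs else 0.0
        return float(v)

    def lo_eq(ncp: float) -> float:
        return sf(ncp) - alpha / 2.0

    def hi_eq(ncp: float) -> float:
        return (1.0 - sf(ncp)) - alpha / 2.0

    # bracket around t_obs; the ncp CI always contains values near t_obs
    span = 10.0 + 2.0 * abs(t_obs)
    lo_bracket = (t_obs - span, t_obs + span)
    while lo_eq(lo_bracket[0]) > 0:
        lo_bracket = (lo_bracket[0] - span, lo_bracket[0])
    while hi_eq(lo_bracket[1]) > 0:
        lo_bracket = (lo_bracket[0], lo_bracket[1] + span)
    lo = optimize.brentq(lo_eq, *lo_bracket, xtol=1e-10)
    hi = optimize.brentq(hi_eq, *lo_bracket, xtol=1e-10)
    return float(lo), float(hi)


def hedges_g_paired(x, y, ci_level: float = 0.95) -> PairedEffect:
    """Paired Hedge's g with a noncentral-t confidence interval.

    g = J * mean(d) / sd(d), with d = x - y, sd with n-1 denominator and
    small-sample correction J = 1 - 3 / (4*df - 1), df = n - 1. The CI is
    obtained by inverting the noncentral-t distribution of the paired t
    statistic for the noncentrality parameter, rescaling by 1/sqrt(n) and J.
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    d = _paired_diffs(x, y)
    n = d.size
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateDataError("differences have zero variance")
    df = n - 1
    cohen_d = float(np.mean(d)) / sd
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    t_obs = cohen_d * math.sqrt(n)
    ncp_lo, ncp_hi = _ncp_confint(t_obs, df, ci_level)
    p = 2.0 * sps.t.sf(abs(t_obs), df)
    return PairedEffect(
        n=n,
        mean_diff=float(np.mean(d)),
        t=t_obs,
        p=float(p),
        g=cohen_d * j,
        g_ci_low=ncp_lo / math.sqrt(n) * j,
        g_ci_high=ncp_hi / math.sqrt(n) * j,
        ci_level=ci_level,
    )


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired data (or differences).

    Zero differences are dropped. Returns ``(W, p)`` where W is the smaller
    of the positive/negative signed-rank sums. Exact p for n <= 25 with no
    ties among |differences|; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    if y is not None:
        d = _paired_diffs(x, y)
    else:
        d = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("differences must be finite")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return w, float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Preserves input order, clips at 1, returns an empty array for empty
    input. Raises for p-values outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_test(x, y) -> tuple[float, float, int]:
    """Spearman rank correlation with a two-sided no-correlation test.

    Pairs with a missing value in either vector are deleted. Requires at
    least 4 complete pairs and non-constant vectors. Returns
    ``(rho, p, n)``. p comes from the t approximation
    ``t = rho*sqrt((n-2)/(1-rho^2))``; when |rho| = 1 that statistic is
    infinite and p is reported as the exact permutation bound 2/n!.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise DegenerateDataError("need at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("constant input vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0 - 1e-15:
        rho = math.copysign(1.0, rho)
        p = 2.0 / math.factorial(n) if n <= 170 else 5e-324
        p = max(p, 5e-324)
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0)), n
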