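"""Cohort statistics: rank tests, correlations, normality, power analysis.

The k-group comparison, independence test and correlation are implemented
directly from their defining formulas (with vetted SciPy distributions for
the reference p-values); Shapiro–Wilk delegates to SciPy's implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidArgumentError


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float
    df: int
    p_value: float
    mean_ranks: tuple[float, ...]
    tie_correction: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    expected: np.ndarray


@dataclass(frozen=True)
class PowerAnalysisSpec:
    """Noncentral chi-square power computation for a given design."""

    effect_size_w: float
    alpha: float
    df: int
    n_total: int
    noncentrality: float
    critical_chi2: float
    power: float


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalWallisResult:
    """Kruskal–Wallis H across k groups with midranks and tie correction.

    p-value from the chi-square approximation with k - 1 degrees of freedom.
    All-identical data across groups gives H = 0, p = 1.
    """
    if len(groups) < 2:
        raise InvalidArgumentError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise InvalidArgumentError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)  # midranks
    mean_ranks = []
    start = 0
    h_sum = 0.0
    for a in arrays:
        r = ranks[start:start + a.size]
        start += a.size
        mr = float(r.mean())
        mean_ranks.append(mr)
        h_sum += a.size * (mr - (n + 1) / 2.0) ** 2
    h = 12.0 / (n * (n + 1)) * h_sum

    # tie correction: 1 - sum(t^3 - t) / (N^3 - N)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))
    correction = 1.0 - tie_term / (n ** 3 - n) if n > 1 else 1.0
    if correction == 0.0:
        # every observation identical; no evidence against homogeneity
        return KruskalWallisResult(0.0, len(arrays) - 1, 1.0,
                                   tuple(mean_ranks), 0.0)
    h /= correction
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df))
    return KruskalWallisResult(float(h), df, p, tuple(mean_ranks), correction)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-tailed t-test on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidArgumentError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError("need n >= 3 for a correlation test")
    if x.std() == 0.0 or y.std() == 0.0:
        raise InvalidArgumentError("correlation undefined for zero-variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p_value=p, n=n)


def chi_square_independence(table: Sequence[Sequence[float]]) -> ChiSquareResult:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InvalidArgumentError("table must be 2-D with >= 2 rows and columns")
    if (obs < 0).any():
        raise InvalidArgumentError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise InvalidArgumentError("degenerate table: zero row or column margin")
    total = obs.sum()
    expected = np.outer(row, col) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquareResult(chi2=chi2, df=df, p_value=float(sps.chi2.sf(chi2, df)),
                           expected=expected)


def chi_square_power(w: float, n_total: int, df: int,
                     alpha: float = 0.05) -> PowerAnalysisSpec:
    """Power of a chi-square test at effect size w with n_total observations.

    Noncentrality lambda = n_total * w**2; power is the upper-tail mass of the
    noncentral chi-square beyond the central (1 - alpha) critical value.
    """
    if w <= 0:
        raise InvalidArgumentError("effect size w must be positive")
    if n_total < 1 or df < 1:
        raise InvalidArgumentError("n_total and df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise InvalidArgumentError("alpha must lie in (0, 1)")
    lam = n_total * w * w
    crit = float(sps.chi2.ppf(1.0 - alpha, df))
    power = float(sps.ncx2.sf(crit, df, lam))
    return PowerAnalysisSpec(effect_size_w=w, alpha=alpha, df=df, n_total=n_total,
                             noncentrality=lam, critical_chi2=crit, power=power)


def required_sample_size(w: float, df: int, alpha: float,
                         target_power: float, n_max: int = 1_000_000) -> int:
    """Smallest n_total whose chi-square power reaches the target."""
    if not alpha < target_power < 1.0:
        raise InvalidArgumentError("target_power must lie in (alpha, 1)")
    n = 1
    while n <= n_max:
        if chi_square_power(w, n, df, alpha).power >= target_power:
            return n
        n += 1
    raise RuntimeError(f"no n <= {n_max} reaches power {target_power}")


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p); delegates to SciPy's routine."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InvalidArgumentError("Shapiro–Wilk requires 3 <= n <= 5000")
    if x.std() == 0.0:
        raise InvalidArgumentError("Shapiro–Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def pooled_summary(group_means: Sequence[float], group_sds: Sequence[float],
                   group_ns: Sequence[int]) -> tuple[float, float]:
    """Pooled mean and SD from per-group summaries.

    Pooled variance uses the sum-of-squares decomposition
    ``[sum (n_i - 1) s_i^2 + sum n_i (m_i - m)^2] / (N - 1)``.
    """
    means = np.asarray(group_means, dtype=float)
    sds = np.asarray(group_sds, dtype=float)
    ns = np.asarray(group_ns, dtype=float)
    if not (means.size == sds.size == ns.size):
        raise InvalidArgumentError("summary lists must have equal length")
    if (ns < 2).any():
        raise InvalidArgumentError("every group needs n >= 2")
    n_total = ns.sum()
    mean = float((ns * means).sum() / n_total)
    ss = ((ns - 1) * sds ** 2).sum() + (ns * (means - mean) ** 2).sum()
    sd = float(math.sqrt(ss / (n_total - 1)))
    return mean, sd
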