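"""Nonparametric group statistics with exact small-sample p-values.

The rank tests here are the package's own implementations (midranks for
ties, exact enumeration of the Mann-Whitney null for small samples, normal
approximation with tie correction otherwise, chi-square approximation for
Kruskal-Wallis); external library routines are used only as cross-checks in
the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "welch_t",
    "significance_stars",
    "EXACT_LIMIT",
]

#: Largest pooled sample size for which the Mann-Whitney null distribution
#: is enumerated exactly.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple
    method: str
    stars: str

    def __post_init__(self):
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def significance_stars(p: float) -> str:
    """Asterisk annotation: *** p < 0.001, ** p < 0.01, * p < 0.05, else
    'ns'.  Boundaries are exclusive, so p = 0.05 exactly is 'ns'."""
    if math.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum()) - n_a * (n_a + 1) / 2.0


def mann_whitney_u(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test (U of the first sample, midranks).

    For pooled sizes up to :data:`EXACT_LIMIT` the p-value is exact: the
    U null distribution is enumerated over all C(n_a+n_b, n_a) group
    labelings of the pooled midranks and the smaller tail is doubled
    (capped at 1).  Larger samples use the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = _u_statistic(ranks[:n_a], n_a)
    mu = n_a * n_b / 2.0

    if n_a + n_b <= EXACT_LIMIT:
        rank_sums = np.array([sum(c) for c in combinations(ranks, n_a)])
        us = rank_sums - n_a * (n_a + 1) / 2.0
        total = us.size
        p_lo = np.count_nonzero(us <= u + 1e-9) / total
        p_hi = np.count_nonzero(us >= u - 1e-9) / total
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        method = "mann-whitney-exact"
    else:
        n = n_a + n_b
        _, t = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(t ** 3 - t)) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            p = 2.0 * norm.sf(max(z, 0.0))
        p = min(1.0, p)
        method = "mann-whitney-normal"
    return TestResult(statistic=u, p_value=p, n_per_group=(n_a, n_b),
                      method=method, stars=significance_stars(p))


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H test with tie correction, p from chi-square with
    k - 1 degrees of freedom.  All-identical data give H = 0, p = 1."""
    samples = [np.asarray(g, float).ravel() for g in groups]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(samples)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start:start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(t ** 3 - t)) / (n ** 3 - n)
    if correction <= 0:
        h, p = 0.0, 1.0
    else:
        h = h / correction
        p = float(chi2.sf(h, df=len(samples) - 1))
    return TestResult(statistic=h, p_value=p,
                      n_per_group=tuple(s.size for s in samples),
                      method="kruskal-wallis", stars=significance_stars(p))


def welch_t(sample_a, sample_b) -> TestResult:
    """Welch two-sample t test (supplementary output alongside the primary
    rank test, since both analyses are of interest for load comparisons)."""
    a = np.asarray(sample_a, float).ravel()
    b = np.asarray(sample_b, float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    denom = math.sqrt(va + vb)
    if denom == 0:
        t, p = 0.0, 1.0
    else:
        t = (a.mean() - b.mean()) / denom
        df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
        from scipy.stats import t as t_dist
        p = 2.0 * float(t_dist.sf(abs(t), df))
    return TestResult(statistic=t, p_value=min(p, 1.0),
                      n_per_group=(a.size, b.size),
                      method="welch-t", stars=significance_stars(min(p, 1.0)))
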