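"""Shared statistical primitives.

The enrichment analyses in this package all reduce to a one-sided
Wilcoxon rank-sum (Mann-Whitney) test of "group counts are greater than
background counts", followed by Bonferroni correction across the taxa
tested simultaneously.  Because prophage counts are small integers, ties
are ubiquitous; the test therefore uses mid-ranks throughout and switches
between an exact permutation enumeration (small groups) and the
tie-corrected normal approximation (everything else).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["wilcoxon_greater", "bonferroni"]

# exact enumeration whenever both groups are at most this size
EXACT_MAX_N = 8


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided p by enumerating every assignment of the pooled
    values to the two groups (mid-ranks, so ties are handled exactly)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    observed = ranks[:n].sum()
    total = 0
    at_least = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-9:
            at_least += 1
    return at_least / total


def wilcoxon_greater(x, y) -> float:
    """One-sided Wilcoxon rank-sum p-value for H1: values in `x` tend to
    be greater than values in `y`.

    Parameters
    ----------
    x, y : array-like
        Observations for the focal group and the background group.

    Returns
    -------
    float
        p-value in [0, 1].  Exact (permutation enumeration over mid-ranks)
        when both groups have at most 8 observations, otherwise the
        tie-corrected normal approximation without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        return _rank_sum_exact_p(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="greater", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)
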