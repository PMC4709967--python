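"""Exact small-sample Wilcoxon tests conditioned on tied midranks.

Both tests enumerate the permutation null *given the observed tied values*:
the signed-rank null is the uniform distribution over the 2^n sign
assignments of the observed |differences|, the rank-sum null the uniform
distribution over the C(N, n1) group relabelings of the observed pooled
values.  Midranks are used for ties, so doubling every rank makes all
statistics integers and the null can be tabulated by dynamic programming
(polynomial convolution) instead of literal enumeration.  Counts stay below
2^53 for the exact regimes used here, so float64 arithmetic is exact.

Beyond the exact-size cutoffs the usual normal approximations with tie
correction and continuity correction are used.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# Exact enumeration bounds: 2^n sign assignments (signed-rank) and
# C(N, n1) relabelings (rank-sum) are tabulated by DP below these sizes.
SIGNED_RANK_EXACT_MAX_N = 25
RANK_SUM_EXACT_MAX_N = 30


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    return stats.rankdata(values, method="average")


def signed_rank_greater(values, reference: float) -> float:
    """One-sample, one-sided Wilcoxon signed-rank p-value for median > reference.

    Zero differences are dropped (Wilcoxon's reduced-sample treatment); if
    every difference is zero the data carry no evidence and p = 1.
    Exact conditional null for n <= 25, tie-corrected normal beyond.
    """
    d = np.asarray(values, dtype=float) - float(reference)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    dbl = np.rint(2.0 * _midranks(np.abs(d))).astype(np.int64)
    w_obs = int(dbl[d > 0].sum())
    if n <= SIGNED_RANK_EXACT_MAX_N:
        total = int(dbl.sum())
        # counts[s] = number of sign assignments with doubled W+ == s
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for r in dbl:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: counts.size - r]
            counts = counts + shifted
        return float(counts[w_obs:].sum() / 2.0**n)
    # normal approximation on the un-doubled statistic
    w = w_obs / 2.0
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(dbl, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (
        (tie_counts**3 - tie_counts).sum() / 48.0
    )
    if var <= 0:
        return 1.0
    z = (w - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def rank_sum_p(x, y, alternative: str) -> float:
    """Two-sample Wilcoxon rank-sum p-value on the group-x rank sum.

    alternative 'less': x tends to be smaller than y; 'greater': larger.
    Exact conditional null (all C(N, n1) relabelings of the pooled tied
    values) for N <= 30, tie-corrected normal approximation beyond.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    dbl = np.rint(2.0 * _midranks(pooled)).astype(np.int64)
    w_obs = int(dbl[:n1].sum())
    N = n1 + n2
    if N <= RANK_SUM_EXACT_MAX_N:
        total = int(dbl.sum())
        # counts[k, s] = number of size-k subsets of the doubled ranks with sum s
        counts = np.zeros((n1 + 1, total + 1))
        counts[0, 0] = 1.0
        for r in dbl:
            nxt = counts.copy()
            nxt[1:, r:] += counts[:-1, : total + 1 - r]
            counts = nxt
        n_subsets = counts[n1].sum()
        if alternative == "less":
            return float(counts[n1, : w_obs + 1].sum() / n_subsets)
        return float(counts[n1, w_obs:].sum() / n_subsets)
    w = w_obs / 2.0
    mean = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(dbl, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    if alternative == "less":
        z = (w - mean + 0.5) / np.sqrt(var)
        return float(stats.norm.cdf(z))
    z = (w - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))
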