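"""Independent brute-force oracles used to pin down the statistical tests.

These deliberately avoid the code paths they check: the Fisher oracle sums
hypergeometric table probabilities over all tables with the observed
margins; the rank-test oracles literally enumerate sign assignments /
group relabelings.
"""

from itertools import combinations

import numpy as np
from scipy import stats

# Relative guard when comparing table probabilities for the two-sided sum:
# mathematically equal pmfs can differ in the last float bit.
_REL = 1e-7


def fisher_oracle(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(two-sided, one-sided 'greater') Fisher p by full-margin enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, N, r1, c1)
    obs = pmf[a - lo]
    two = pmf[pmf <= obs * (1 + _REL)].sum()
    greater = pmf[ks >= a].sum()
    return min(float(two), 1.0), min(float(greater), 1.0)


def signed_rank_oracle(values, reference: float) -> float:
    """One-sided (greater) signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(values, float) - reference
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


def rank_sum_oracle(x, y, alternative: str) -> float:
    """One-sided rank-sum p by enumerating all C(N, n1) group assignments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = x.size
    w_obs = ranks[:n1].sum()
    count = total = 0
    for idx in combinations(range(pooled.size), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if alternative == "less" and w <= w_obs + 1e-9:
            count += 1
        elif alternative == "greater" and w >= w_obs - 1e-9:
            count += 1
    return count / total


def hypergeom_tail_oracle(M: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n) by direct term summation."""
    from math import comb

    total = comb(M, n)
    return sum(
        comb(K, j) * comb(M - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def bh_oracle(pvals):
    """Benjamini-Hochberg adjusted p by the textbook step-up recursion."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        r = m - rank_from_top
        prev = min(prev, p[i] * m / r)
        adj[i] = prev
    return adj
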