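"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: Fisher p-values
come from exact integer hypergeometric enumeration, rank-sum p-values from
explicit enumeration of group assignments, and skewness from direct central
moments.
"""

from itertools import combinations
from math import comb

import numpy as np


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration over fixed margins.

    All tables with the observed margins are enumerated; those whose
    hypergeometric probability (compared exactly, as integers over a common
    denominator) does not exceed the observed one contribute to p.
    """
    r1, r2 = a + b, c + d
    n = r1 + r2
    col1 = a + c
    denom = comb(n, col1)
    num_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, col1 - r2), min(r1, col1) + 1):
        num = comb(r1, x) * comb(r2, col1 - x)
        if num <= num_obs:
            total += num
    return total / denom


def rank_sum_enumeration(x, y) -> float:
    """Two-sided rank-sum p by enumerating all group assignments.

    For tie-free data the two-sided p-value is the fraction of assignments
    whose U statistic is at least as far from the null mean as observed.
    """
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    m = n1 * n2

    def u_of(rank_sum: float) -> float:
        return rank_sum - n1 * (n1 + 1) / 2

    u_obs = u_of(sum(ranks[v] for v in x))
    dev_obs = abs(u_obs - m / 2)
    hits = 0
    total = 0
    for subset in combinations(range(1, n1 + n2 + 1), n1):
        u = u_of(sum(subset))
        total += 1
        if abs(u - m / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def skewness_moments(values) -> float:
    """g1 skewness from direct central moments."""
    x = np.asarray(values, dtype=float)
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    m3 = ((x - mu) ** 3).mean()
    return m3 / m2 ** 1.5


def ks_statistic_direct(values, cdf) -> float:
    """One-sample KS D by direct ECDF comparison at the sample points."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    f = cdf(x)
    d_plus = np.max(np.arange(1, n + 1) / n - f)
    d_minus = np.max(f - np.arange(0, n) / n)
    return max(d_plus, d_minus)
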