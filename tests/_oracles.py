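"""Brute-force reference implementations used only by the tests.

These stay independent of the package code paths they check: exhaustive
sign-assignment enumeration for the signed-rank test, full hypergeometric
enumeration for Fisher's exact test, the literal step-up definition of
Benjamini-Hochberg, and exhaustive label partitioning for PERMANOVA.
"""

from itertools import combinations, product
from math import comb

import numpy as np


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = _rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_lo = min(w_obs, total - w_obs)
    w_hi = total - w_lo
    hits = 0
    for signs in product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w <= w_lo + 1e-9 or w >= w_hi - 1e-9:
            hits += 1
    return hits / 2 ** n


def _rankdata(a):
    order = np.argsort(a)
    ranks = np.empty(len(a), dtype=float)
    i = 0
    sorted_a = a[order]
    while i < len(a):
        j = i
        while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def fisher_exact_p(table) -> float:
    """Two-sided Fisher p by summing hypergeometric pmfs <= observed."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0

    def pmf(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def bh_stepup(pvalues) -> np.ndarray:
    """Literal BH definition: q_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, m / (i + 1) * p[order[i]])
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def permanova_exhaustive_p(d2: np.ndarray, n_a: int) -> float:
    """Exact PERMANOVA p for two groups by enumerating all label partitions."""
    n = d2.shape[0]

    def pseudo_f(idx_a):
        idx_a = np.asarray(idx_a)
        idx_b = np.setdiff1d(np.arange(n), idx_a)
        sst = d2.sum() / (2 * n)
        ssw = (d2[np.ix_(idx_a, idx_a)].sum() / (2 * len(idx_a))
               + d2[np.ix_(idx_b, idx_b)].sum() / (2 * len(idx_b)))
        return (sst - ssw) / 1 / (ssw / (n - 2))

    f_obs = pseudo_f(np.arange(n_a))
    fs = [pseudo_f(list(c)) for c in combinations(range(n), n_a)]
    return sum(f >= f_obs - 1e-12 for f in fs) / len(fs)
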