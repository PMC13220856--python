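"""Independent reference implementations used only to check the package.

Everything here is written the slow, obvious way (explicit loops and
full enumerations) so that agreement with the vectorized production
code is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_force_clusters(sequences: list[str], max_dist: int) -> list[set[int]]:
    """Connected components under the pairwise Hamming <= max_dist graph,
    within exact-length groups, via naive union-find."""
    parent = list(range(len(sequences)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(sequences)), 2):
        if len(sequences[i]) != len(sequences[j]):
            continue
        if brute_force_hamming(sequences[i], sequences[j]) <= max_dist:
            parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(len(sequences)):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def mi_brute_force(bases: np.ndarray, levels: np.ndarray) -> float:
    """Mutual information (bits) of two discrete samples, cell by cell."""
    n = len(bases)
    assert n == len(levels)
    total = 0.0
    for b in sorted(set(bases.tolist())):
        for f in sorted(set(levels.tolist())):
            joint = sum(
                1 for x, y in zip(bases, levels) if x == b and y == f
            ) / n
            if joint == 0:
                continue
            pb = sum(1 for x in bases if x == b) / n
            pf = sum(1 for y in levels if y == f) / n
            total += joint * math.log2(joint / (pb * pf))
    return total


def mwu_u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x over y, counting ties as 1/2 (no ties in oracle usage)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mwu_null_distribution(m: int, n: int) -> np.ndarray:
    """Counts of arrangements per U value under the exact null.

    f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u): the largest observation
    belongs to x (contributing n to U) or to y.
    """
    table = {(0, 0): np.array([1.0])}
    for mm in range(m + 1):
        for nn in range(n + 1):
            if (mm, nn) in table:
                continue
            size = mm * nn + 1
            dist = np.zeros(size)
            if mm > 0:
                prev = table[(mm - 1, nn)]
                dist[nn : nn + prev.size] += prev
            if nn > 0:
                prev = table[(mm, nn - 1)]
                dist[: prev.size] += prev
            table[(mm, nn)] = dist
    return table[(m, n)]


def mwu_exact_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p-value from the full U distribution."""
    u = mwu_u_statistic(np.asarray(x), np.asarray(y))
    dist = mwu_null_distribution(len(x), len(y))
    total = dist.sum()
    k = int(round(u))
    p_ge = dist[k:].sum() / total
    p_le = dist[: k + 1].sum() / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def mwu_exact_by_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by literally enumerating every group assignment."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    m = len(x)
    u_obs = mwu_u_statistic(x, y)
    n_ge = n_le = n_all = 0
    for combo in itertools.combinations(range(len(pooled)), m):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(combo)] = True
        u = mwu_u_statistic(pooled[mask], pooled[~mask])
        n_all += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
        if u <= u_obs + 1e-9:
            n_le += 1
    return min(1.0, 2.0 * min(n_ge / n_all, n_le / n_all))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for [[a, b], [c, d]] by hypergeometric
    summation of all tables no more probable than the observed one."""
    from scipy.stats import hypergeom

    row1, col1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, row1, col1)
    p_obs = rv.pmf(a)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        p = rv.pmf(k)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, the textbook step-up way."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p, kind="stable")
    n = p.size
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q
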