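"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: subset search by
exhaustive combination enumeration, labeling by flood fill, permutation
p-values by direct enumeration with textbook statistics.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def brightest_connected_oracle(volume: np.ndarray, mask: np.ndarray, k: int = 5,
                               connectivity: int = 26) -> float:
    """Max mean over all connected k-subsets, by enumerating every combination."""
    coords = np.argwhere(mask)
    values = volume[mask]
    n = len(coords)
    if n <= k:
        return float(values.mean())
    diff = np.abs(coords[:, None, :] - coords[None, :, :])
    cheb = diff.max(axis=2)
    manh = diff.sum(axis=2)
    if connectivity == 26:
        adj = cheb == 1
    elif connectivity == 18:
        adj = (cheb == 1) & (manh <= 2)
    elif connectivity == 6:
        adj = manh == 1
    else:
        raise ValueError(connectivity)
    combos = np.array(list(itertools.combinations(range(n), k)))
    sub = adj[combos[:, :, None], combos[:, None, :]]
    reach = np.zeros((len(combos), k), bool)
    reach[:, 0] = True
    for _ in range(k - 1):
        reach |= np.einsum("mjk,mk->mj", sub, reach) > 0
    connected = reach.all(axis=1)
    assert connected.any(), "no connected subset in oracle instance"
    return float(values[combos].mean(axis=1)[connected].max())


def flood_fill_labels(binary: np.ndarray, connectivity: int = 18) -> list[int]:
    """Connected-component sizes via BFS flood fill; returns sorted sizes."""
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        order = sum(abs(x) for x in d)
        if d == (0, 0, 0):
            continue
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offsets.append(d)
    visited = np.zeros(binary.shape, bool)
    sizes = []
    for start in map(tuple, np.argwhere(binary)):
        if visited[start]:
            continue
        size = 0
        queue = deque([start])
        visited[start] = True
        while queue:
            p = queue.popleft()
            size += 1
            for off in offsets:
                q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                if all(0 <= q[i] < binary.shape[i] for i in range(3)) and binary[q] and not visited[q]:
                    visited[q] = True
                    queue.append(q)
        sizes.append(size)
    return sorted(sizes)


def one_way_F(y: np.ndarray, groups: np.ndarray) -> float:
    """Textbook one-way ANOVA F (between/within mean squares)."""
    levels = sorted(set(groups.tolist()))
    grand = y.mean()
    ssb = sum(len(y[groups == g]) * (y[groups == g].mean() - grand) ** 2 for g in levels)
    ssw = sum(((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in levels)
    df1, df2 = len(levels) - 1, len(y) - len(levels)
    if ssw == 0:
        return 0.0 if ssb == 0 else math.inf
    return float((ssb / df1) / (ssw / df2))


def exhaustive_anova_p(y: np.ndarray, groups: np.ndarray) -> tuple[float, int]:
    """Exact permutation p for the one-way F over all distinct relabelings."""
    from sympy.utilities.iterables import multiset_permutations

    f_obs = one_way_F(y, groups)
    count = total = 0
    for labels in multiset_permutations(list(groups)):
        total += 1
        if one_way_F(y, np.array(labels)) >= f_obs - 1e-12:
            count += 1
    return count / total, total


def welchless_t(y: np.ndarray, groups: np.ndarray, a: str, b: str) -> float:
    """Pooled-variance two-sample t statistic (a minus b)."""
    ya, yb = y[groups == a], y[groups == b]
    na, nb = len(ya), len(yb)
    sp2 = (((ya - ya.mean()) ** 2).sum() + ((yb - yb.mean()) ** 2).sum()) / (na + nb - 2)
    return float((ya.mean() - yb.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb)))


def exhaustive_two_group_t_p(y: np.ndarray, groups: np.ndarray, a: str, b: str) -> tuple[float, int]:
    """Exact one-tailed (a > b) permutation p over all distinct relabelings."""
    from sympy.utilities.iterables import multiset_permutations

    t_obs = welchless_t(y, groups, a, b)
    count = total = 0
    for labels in multiset_permutations(list(groups)):
        total += 1
        if welchless_t(y, np.array(labels), a, b) >= t_obs - 1e-12:
            count += 1
    return count / total, total


def spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Spearman p by full enumeration, via scipy's rho."""
    from scipy import stats

    rho_obs = abs(stats.spearmanr(x, y).statistic)
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(stats.spearmanr(x, perm).statistic) >= rho_obs - 1e-12:
            count += 1
    return count / total
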