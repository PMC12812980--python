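"""Brute-force reference implementations used only by the tests.

Each oracle is written as directly as possible from the defining formula —
independent of the library code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.sparse.csgraph import connected_components, floyd_warshall


def average_ranks(x) -> list[float]:
    """Average ranks by explicit position counting (1-based)."""
    x = list(x)
    out = []
    for xi in x:
        less = sum(1 for v in x if v < xi)
        equal = sum(1 for v in x if v == xi)
        # positions less+1 .. less+equal share the average rank
        out.append(less + (equal + 1) / 2.0)
    return out


def pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / math.sqrt((a * a).sum() * (b * b).sum()))


def spearman(x, y) -> float:
    return pearson(average_ranks(x), average_ranks(y))


def bh_qvalues(p) -> list[float]:
    """Literal step-up definition: q_i = min_{j: p_(j) >= p_i} m p_(j) / j."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    sorted_p = [p[i] for i in order]
    q = []
    for pi in p:
        candidates = [
            m * sorted_p[j] / (j + 1)
            for j in range(m)
            if sorted_p[j] >= pi - 1e-15
        ]
        q.append(min(1.0, min(candidates)))
    return q


def shannon(counts) -> float:
    total = float(sum(counts))
    h = 0.0
    for c in counts:
        if c > 0:
            pi = c / total
            h -= pi * math.log(pi)
    return h


def bray_curtis(x, y) -> float:
    num = 2.0 * sum(min(a, b) for a, b in zip(x, y))
    den = sum(x) + sum(y)
    return 1.0 - num / den


def set_partitions(items):
    """All partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [first]] + partition[i + 1:]
        yield [[first]] + partition


def modularity(edges, partition, nodes) -> float:
    """Newman modularity of an undirected simple graph from first principles."""
    m = len(edges)
    degree = {v: 0 for v in nodes}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    community = {}
    for ci, comm in enumerate(partition):
        for v in comm:
            community[v] = ci
    q = 0.0
    for ci in range(len(partition)):
        e_c = sum(1 for u, v in edges if community[u] == ci and community[v] == ci)
        d_c = sum(d for v, d in degree.items() if community[v] == ci)
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def max_modularity(edges, nodes) -> float:
    """Exhaustive search over all partitions (feasible for <= 8 nodes)."""
    best = -math.inf
    for partition in set_partitions(list(nodes)):
        best = max(best, modularity(edges, partition, nodes))
    return best


def path_metrics(adjacency: np.ndarray):
    """(diameter, average path length) on the largest component, via
    Floyd–Warshall on the unweighted graph."""
    n_comp, labels = connected_components(adjacency, directed=False)
    sizes = np.bincount(labels)
    giant = np.flatnonzero(labels == np.argmax(sizes))
    sub = adjacency[np.ix_(giant, giant)].astype(float)
    sub[sub == 0] = np.inf
    np.fill_diagonal(sub, 0.0)
    d = floyd_warshall(sub, directed=False, unweighted=True)
    iu = np.triu_indices(len(giant), k=1)
    vals = d[iu]
    if vals.size == 0:
        return 0, 0.0
    return int(vals.max()), float(vals.mean())


def mantel_exact(d1: np.ndarray, d2: np.ndarray) -> tuple[float, float]:
    """(r_obs, exact one-tailed p) by full enumeration of label permutations,
    Spearman statistic via scipy on the upper triangles."""
    from scipy.stats import spearmanr

    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = spearmanr(d1[iu], d2[iu]).statistic
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        idx = np.asarray(perm)
        r_p = spearmanr(d1[iu], d2[np.ix_(idx, idx)][iu]).statistic
        if r_p >= r_obs - 1e-12:
            count += 1
        total += 1
    return float(r_obs), count / total
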