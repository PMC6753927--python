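"""Independent brute-force oracles used to validate the library.

Everything here is deliberately naive (neighbor-set enumeration, BFS by
hand, full double sums, exhaustive permutation enumeration) and shares no
code path with the implementations it checks.
"""
from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def _adjacency(nodes, edges):
    nbrs = {n: set() for n in nodes}
    for u, v in edges:
        nbrs[u].add(v)
        nbrs[v].add(u)
    return nbrs


def oracle_clustering(nodes, edges, count_zeros=True):
    nbrs = _adjacency(nodes, edges)
    eset = {frozenset(e) for e in edges}
    coeffs = []
    for n in nodes:
        k = len(nbrs[n])
        if k < 2:
            if count_zeros:
                coeffs.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(sorted(nbrs[n]), 2)
                    if frozenset((a, b)) in eset)
        coeffs.append(2.0 * links / (k * (k - 1)))
    return sum(coeffs) / len(coeffs)


def oracle_cpl(nodes, edges):
    nbrs = _adjacency(nodes, edges)
    means = []
    for src in nodes:
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in nbrs[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        reach = [d for n, d in dist.items() if n != src]
        if reach:
            means.append(sum(reach) / len(reach))
    return float(np.median(means))


def oracle_density(nodes, edges):
    n = len(nodes)
    return 2.0 * len(edges) / (n * (n - 1))


def oracle_heterogeneity(nodes, edges):
    nbrs = _adjacency(nodes, edges)
    deg = np.array([len(nbrs[n]) for n in nodes], dtype=float)
    return float(np.sqrt(((deg - deg.mean()) ** 2).mean()) / deg.mean())


def oracle_modularity(nodes, edges, assignment):
    """Q via the full double sum (1/2m) sum_ij (A_ij - k_i k_j/2m) delta."""
    nodes = list(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    k = a.sum(axis=1)
    m2 = a.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[nodes[i]] == assignment[nodes[j]]:
                q += a[i, j] - k[i] * k[j] / m2
    return q / m2


def _spearman(x, y):
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))


def _triangle(m):
    m = np.asarray(m)
    return m[np.triu_indices(m.shape[0], 1)]


def oracle_mantel_exact(dx, dy):
    """Exact one-sided-greater Mantel p by enumerating all n! relabelings."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    n = dx.shape[0]
    x = _triangle(dx)
    r_obs = _spearman(x, _triangle(dy))
    count = total = 0
    for perm in itertools.permutations(range(n)):
        perm = list(perm)
        r = _spearman(x, _triangle(dy[np.ix_(perm, perm)]))
        count += r >= r_obs - 1e-12
        total += 1
    return r_obs, count / total


def oracle_permanova(d, labels):
    """Direct SS decomposition -> (F, R2); no permutation."""
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    groups = sorted(set(labels.tolist()))
    a = len(groups)
    d2 = d ** 2
    sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ssw += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ssb = sst - ssw
    f = (ssb / (a - 1)) / (ssw / (n - a))
    return f, ssb / sst


def oracle_permanova_exact_p(d, labels):
    """Exact PERMANOVA p over all distinct label orderings (small n only)."""
    f_obs, _ = oracle_permanova(d, labels)
    n = len(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        f, _ = oracle_permanova(d, np.asarray(labels)[list(perm)])
        count += f >= f_obs - 1e-12
        total += 1
    return count / total
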