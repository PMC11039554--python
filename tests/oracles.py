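"""Brute-force graph-metric oracles, independent of the package internals.

Everything here is written for clarity and exhaustiveness on tiny graphs
(<= ~12 nodes): explicit Floyd-Warshall distances, path enumeration for
betweenness, power iteration for the principal eigenvector, and full
set-partition search for maximum modularity.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_path_length(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("inf")


def brute_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def _count_shortest_paths(adj: np.ndarray, s: int, t: int, d: np.ndarray):
    """Enumerate all shortest s-t paths; returns list of paths (node tuples)."""
    if not np.isfinite(d[s, t]):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in np.flatnonzero(adj[u]):
            # v lies on a shortest path iff it advances toward t
            if d[s, u] + 1 + d[v, t] == d[s, t] and d[s, v] == d[s, u] + 1:
                extend(path + [v])

    extend([s])
    return paths


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness by explicit shortest-path enumeration."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _count_shortest_paths(adj, s, t, d)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def brute_eigenvector(adj: np.ndarray, iters: int = 20000) -> np.ndarray:
    """Principal eigenvector by power iteration, scaled to max 1.

    Iterates on A + I so the spectrum is nonnegative: on bipartite
    graphs plain power iteration oscillates between the +/-lambda pair.
    The shift leaves eigenvectors unchanged.
    """
    v = np.ones(adj.shape[0])
    a = adj.astype(float) + np.eye(adj.shape[0])
    for _ in range(iters):
        nv = a @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return v * 0
        nv = nv / norm
        if np.abs(nv - v).max() < 1e-14:
            v = nv
            break
        v = nv
    return v / v.max()


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1 :]
        yield [[first]] + part


def modularity_q(adj: np.ndarray, partition) -> float:
    m2 = adj.sum()  # 2m
    deg = adj.sum(axis=1)
    q = 0.0
    for block in partition:
        for i in block:
            for j in block:
                q += adj[i, j] - deg[i] * deg[j] / m2
    return q / m2


def brute_max_modularity(adj: np.ndarray) -> float:
    nodes = list(range(adj.shape[0]))
    return max(modularity_q(adj, p) for p in set_partitions(nodes))


def brute_assortativity(adj: np.ndarray) -> float:
    """Newman's degree assortativity from the edge list."""
    deg = adj.sum(axis=1)
    i, j = np.nonzero(np.triu(adj, 1))
    if i.size == 0:
        return float("nan")
    jk = deg[i] * deg[j]
    half_sum = 0.5 * (deg[i] + deg[j])
    half_sq = 0.5 * (deg[i] ** 2 + deg[j] ** 2)
    m = float(i.size)
    num = jk.mean() - half_sum.mean() ** 2
    den = half_sq.mean() - half_sum.mean() ** 2
    return float(num / den) if den != 0 else float("nan")


def gaussian_symmetric_kld(mu1, s1, mu2, s2) -> float:
    """Closed-form Jeffreys divergence between two univariate Gaussians."""
    term = 0.5 * (s1**2 + (mu1 - mu2) ** 2) / s2**2 + 0.5 * (
        s2**2 + (mu1 - mu2) ** 2
    ) / s1**2 - 1.0
    return term
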