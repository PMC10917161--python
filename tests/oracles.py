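"""Independent brute-force oracles for binary graph metrics.

Deliberately naive: triple enumeration for triangles, Floyd-Warshall for
distances, and explicit enumeration of every shortest path for betweenness.
Nothing here shares code with the package implementations.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np


def bf_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def bf_distances(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = bf_distances(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def bf_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        out[i] = bf_global_efficiency(sub)
    return out


def _all_shortest_paths(adj: np.ndarray, dist: np.ndarray, s: int, t: int):
    """Every shortest s-t path, found by walking distance-to-t downhill."""
    n = adj.shape[0]
    paths = []

    def extend(u, path):
        if u == t:
            paths.append(path)
            return
        for v in range(n):
            if adj[u, v] and dist[v, t] == dist[u, t] - 1:
                extend(v, path + [v])

    extend(s, [s])
    return paths


def bf_betweenness(adj: np.ndarray, normalized: bool = False) -> np.ndarray:
    n = adj.shape[0]
    dist = bf_distances(adj)
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]) or dist[s, t] == 0:
                continue
            paths = _all_shortest_paths(adj, dist, s, t)
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    if normalized:
        denom = (n - 1) * (n - 2) / 2.0
        bc = bc / denom if denom > 0 else np.zeros(n)
    return bc


def random_adjacency(rng: np.random.Generator, n: int,
                     m: int | None = None) -> np.ndarray:
    """Random simple graph on n nodes; m edges if given, else density ~0.5."""
    pairs = list(combinations(range(n), 2))
    if m is None:
        m = rng.integers(0, len(pairs) + 1)
    chosen = rng.choice(len(pairs), size=m, replace=False)
    adj = np.zeros((n, n), dtype=np.int8)
    for idx in chosen:
        i, j = pairs[idx]
        adj[i, j] = adj[j, i] = 1
    return adj
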