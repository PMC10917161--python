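"""Binary undirected graph metrics: clustering, efficiency, betweenness.

All metrics operate on the 0/1 adjacency of a proportionally thresholded
connectivity matrix and follow the Brain Connectivity Toolbox conventions
for degenerate cases so values are comparable with the wider literature:

* clustering coefficient ``C_i = 2 t_i / (k_i (k_i - 1))`` with ``C_i = 0``
  for degree < 2; the global coefficient ``C`` is the mean of the ``C_i``;
* global efficiency ``E`` is the mean inverse shortest path length over
  ordered node pairs, disconnected pairs contributing 0 — no connectivity
  precondition is imposed because half-density graphs at coarse scales can
  be disconnected;
* local efficiency ``E_i`` is ``E`` of the subgraph induced on node i's
  neighbours (``0`` for degree < 2);
* betweenness centrality ``B_i`` is the fraction of all-pairs shortest
  paths passing through i, computed with Brandes' single-source
  accumulation (graphs are unweighted, so BFS suffices), normalised by
  ``(N-1)(N-2)/2`` by default.

Everything is implemented here directly; no graph library is imported.
"""
from __future__ import annotations

from collections import deque
from typing import Sequence, Union

import numpy as np

from .containers import BinaryGraph, GlobalMetrics, NodeMetricVector

_Graph = Union[BinaryGraph, np.ndarray]


def _adjacency(g: _Graph) -> np.ndarray:
    a = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    return a.astype(np.int8)


def _wrap(g: _Graph, name: str, values: np.ndarray) -> NodeMetricVector:
    if isinstance(g, BinaryGraph):
        return NodeMetricVector(metric_name=name, values=values,
                                node_ids=g.node_ids, scale=g.scale,
                                subject_id=g.subject_id)
    return NodeMetricVector(metric_name=name, values=values,
                            node_ids=np.arange(values.size), scale=0,
                            subject_id="")


def clustering_coefficients(g: _Graph) -> NodeMetricVector:
    """Per-node fraction of neighbour pairs that are themselves connected."""
    a = _adjacency(g).astype(np.int64)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return _wrap(g, "clustering", c)


def global_clustering(g: _Graph) -> float:
    """Mean of the per-node clustering coefficients."""
    return float(clustering_coefficients(g).values.mean())


def shortest_path_lengths(g: _Graph) -> np.ndarray:
    """All-pairs unweighted distances by BFS; np.inf for disconnected pairs."""
    a = _adjacency(g)
    n = a.shape[0]
    neighbors = [np.nonzero(a[i])[0] for i in range(n)]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0.0
        q = deque([s])
        while q:
            u = q.popleft()
            du = dist[s, u]
            for v in neighbors[u]:
                if np.isinf(dist[s, v]):
                    dist[s, v] = du + 1.0
                    q.append(v)
    return dist


def global_efficiency(g: _Graph) -> float:
    """Mean inverse shortest path length over ordered pairs (0 if N < 2)."""
    a = _adjacency(g)
    n = a.shape[0]
    if n < 2:
        return 0.0
    dist = shortest_path_lengths(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(g: _Graph) -> NodeMetricVector:
    """Global efficiency of each node's neighbour-induced subgraph."""
    a = _adjacency(g)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.nonzero(a[i])[0]
        if nb.size < 2:
            continue
        out[i] = global_efficiency(a[np.ix_(nb, nb)])
    return _wrap(g, "local_efficiency", out)


def betweenness_centrality(g: _Graph, normalized: bool = True) -> NodeMetricVector:
    """Brandes' betweenness for unweighted undirected graphs.

    Raw values count each unordered (s, t) pair once; normalisation divides
    by (N-1)(N-2)/2, the count of pairs that could route through a node.
    """
    a = _adjacency(g)
    n = a.shape[0]
    neighbors = [np.nonzero(a[i])[0] for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest-path DAG
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order = []
        q = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for v in neighbors[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        # back-propagate dependencies
        delta = np.zeros(n)
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0                                  # each unordered pair counted twice
    if normalized:
        denom = (n - 1) * (n - 2) / 2.0
        bc = bc / denom if denom > 0 else np.zeros(n)
    return _wrap(g, "betweenness", bc)


def global_metrics(g: BinaryGraph) -> GlobalMetrics:
    """Global clustering C and global efficiency E for one graph."""
    return GlobalMetrics(
        global_clustering=global_clustering(g),
        global_efficiency=global_efficiency(g),
        scale=g.scale, subject_id=g.subject_id,
    )


def node_metrics(g: BinaryGraph, normalized_betweenness: bool = True
                 ) -> list[NodeMetricVector]:
    """All three node metrics for one graph, in a fixed order."""
    return [
        clustering_coefficients(g),
        local_efficiency(g),
        betweenness_centrality(g, normalized=normalized_betweenness),
    ]


def write_metric_tsv(vectors: Sequence[NodeMetricVector], path) -> None:
    """Tidy TSV: subject_id, scale, node_id, metric_name, value."""
    from .containers import metrics_to_frame

    metrics_to_frame(vectors).to_csv(path, sep="\t", index=False,
                                     float_format="%.8g")
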