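"""Node time courses, Pearson connectivity, and proportional thresholding.

For each subject and scale the pipeline averages voxel time courses within
each parcel, correlates every node pair (Pearson's r, diagonal zeroed) and
binarizes the matrix by keeping the proportion P of strongest connections
as unweighted edges. "Strongest" ranks the signed correlation by default
(the Brain Connectivity Toolbox convention — a strongly negative
correlation is not an edge); ``mode="absolute"`` ranks |r| instead.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasHierarchy
from .containers import BinaryGraph, ConnectivityMatrix, SubjectTimeseries
from .errors import DegenerateInputError, EmptyNodeError


def extract_node_timecourses(ts: SubjectTimeseries, labels: np.ndarray,
                             h: AtlasHierarchy, scale: int) -> SubjectTimeseries:
    """Average voxel series into node series at ``scale``.

    ``labels`` gives the finest-scale parcel of each unit (column) of ``ts``;
    zeros mark background units and are ignored. Node order follows the
    atlas order at the requested scale.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != ts.n_units:
        raise ValueError("labels must align with the subject's units")
    coarse = h.coarsen_labels(labels.astype(int), scale)
    node_ids = h.node_ids(scale)
    names = dict(zip(node_ids, h.node_names(scale)))
    out = np.empty((ts.n_timepoints, len(node_ids)))
    for j, nid in enumerate(node_ids):
        members = coarse == nid
        if not members.any():
            raise EmptyNodeError(
                f"parcel {names[int(nid)]} (id {int(nid)}, scale {scale}) has no voxels")
        out[:, j] = ts.data[:, members].mean(axis=1)
    return SubjectTimeseries(
        data=out, tr_seconds=ts.tr_seconds, unit_ids=node_ids,
        subject_id=ts.subject_id, group=ts.group, scale=scale,
    )


def pearson_connectivity(node_ts: SubjectTimeseries) -> ConnectivityMatrix:
    """Pearson correlation between every node pair; diagonal set to 0."""
    x = node_ts.data
    if x.shape[0] < 3:
        raise DegenerateInputError("need at least 3 time points for correlation")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = node_ts.unit_ids[sd == 0]
        raise DegenerateInputError(f"zero-variance node series: {bad.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        values=r, node_ids=node_ts.unit_ids,
        scale=node_ts.scale if node_ts.scale is not None else 1,
        subject_id=node_ts.subject_id,
    )


def edge_budget(n_nodes: int, p: float) -> int:
    """round(P * N(N-1)/2) with half-up rounding, so odd pair counts are fixed."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(p * n_pairs + 0.5))


def proportional_threshold(m: ConnectivityMatrix, p: float,
                           mode: str = "signed") -> BinaryGraph:
    """Keep the top round(P * N(N-1)/2) strongest pairs as unweighted edges.

    Ranking is by signed value (default) or absolute value, descending; ties
    at the cutoff break by (row, column) order so results are deterministic.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    n = m.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    vals = m.values[iu, ju]
    if mode == "absolute":
        vals = np.abs(vals)
    n_edges = edge_budget(n, p)
    adj = np.zeros((n, n), dtype=np.int8)
    if n_edges > 0:
        # stable sort on -vals keeps row-major (row, col) order within ties
        order = np.argsort(-vals, kind="stable")[:n_edges]
        adj[iu[order], ju[order]] = 1
        adj |= adj.T
    return BinaryGraph(adjacency=adj, node_ids=m.node_ids, scale=m.scale,
                       retained_fraction=float(p), subject_id=m.subject_id)


# ---------------------------------------------------------------------------
# TSV I/O

def write_matrix_tsv(m: ConnectivityMatrix, path) -> None:
    """Square matrix with node-id header row and index column."""
    ids = [str(int(i)) for i in m.node_ids]
    pd.DataFrame(m.values, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.8g")


def read_matrix_tsv(path, scale: int = 1, subject_id: str = "") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(), node_ids=np.array([int(c) for c in df.columns]),
        scale=scale, subject_id=subject_id)


def write_edge_list_tsv(g: BinaryGraph, path) -> None:
    iu, ju = np.nonzero(np.triu(g.adjacency, k=1))
    pd.DataFrame({"source": g.node_ids[iu], "target": g.node_ids[ju]}).to_csv(
        path, sep="\t", index=False)


def connectivity_stack(mats: Sequence[ConnectivityMatrix]) -> np.ndarray:
    """Stack same-scale matrices into (n_subjects, N, N); validates shapes."""
    shapes = {m.values.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"matrices have mixed shapes: {shapes}")
    return np.stack([m.values for m in mats])
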