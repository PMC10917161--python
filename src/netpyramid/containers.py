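"""Shared in-memory containers for time series, connectivity and node metrics.

These are thin dataclasses around numpy arrays; heavy lifting lives in the
operation modules. All node-level containers keep an explicit ``node_ids``
vector so values stay aligned to atlas parcels regardless of array order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class SubjectTimeseries:
    """One subject's time-ordered signal matrix (time x units).

    Units are voxels (with ``unit_labels`` giving the finest-scale parcel of
    each voxel) or atlas nodes at one scale (``unit_labels`` is None and
    ``scale`` is set).
    """

    data: np.ndarray                 # (n_timepoints, n_units), float
    tr_seconds: float
    unit_ids: np.ndarray             # (n_units,), int identifiers
    subject_id: str
    group: str                       # "patient" or "control"
    unit_labels: Optional[np.ndarray] = None   # finest parcel id per voxel
    scale: Optional[int] = None                # set for node-level series

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x units)")
        if self.data.shape[1] != self.unit_ids.shape[0]:
            raise ValueError("unit_ids length must match number of columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with zeroed diagonal."""

    values: np.ndarray               # (N, N) float
    node_ids: np.ndarray
    scale: int
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(self.values[~np.eye(n, dtype=bool)]) > 1 + 1e-9):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph from proportional thresholding."""

    adjacency: np.ndarray            # (N, N) of {0, 1}
    node_ids: np.ndarray
    scale: int
    retained_fraction: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.astype(bool).astype(a.dtype)):
            raise ValueError("adjacency must be 0/1")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)
        self.node_ids = np.asarray(self.node_ids)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class NodeMetricVector:
    """Per-node values of one metric for one subject at one scale."""

    metric_name: str                 # clustering | local_efficiency | betweenness | alff
    values: np.ndarray
    node_ids: np.ndarray
    scale: int
    subject_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        if self.values.shape != self.node_ids.shape:
            raise ValueError("values and node_ids must align")


@dataclass
class GlobalMetrics:
    """Whole-graph summaries: mean clustering C and global efficiency E."""

    global_clustering: float
    global_efficiency: float
    scale: int
    subject_id: str


@dataclass
class AlffMap:
    """Per-unit low-frequency amplitude, optionally z-scored across units."""

    values: np.ndarray
    unit_ids: np.ndarray
    band: tuple[float, float]
    normalized: bool
    subject_id: str
    unit_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        if not self.normalized and np.any(self.values < 0):
            raise ValueError("raw amplitude values must be non-negative")


def metrics_to_frame(vectors: Sequence[NodeMetricVector]):
    """Stack node metric vectors into a tidy table.

    Columns: subject_id, scale, node_id, metric_name, value.
    """
    import pandas as pd

    frames = []
    for v in vectors:
        frames.append(pd.DataFrame({
            "subject_id": v.subject_id,
            "scale": v.scale,
            "node_id": v.node_ids,
            "metric_name": v.metric_name,
            "value": v.values,
        }))
    if not frames:
        return pd.DataFrame(
            columns=["subject_id", "scale", "node_id", "metric_name", "value"])
    return pd.concat(frames, ignore_index=True)
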