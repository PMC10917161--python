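"""Amplitude of low-frequency fluctuations (ALFF) and node averaging.

ALFF of a unit is the sum of single-sided DFT amplitude moduli over the
bins inside the passband (0.01-0.1 Hz by default, endpoints inclusive, DC
excluded). Amplitude of bin k is ``2/n * |X_k|``, the convention under
which a sinusoid of amplitude A at a bin frequency contributes exactly A.
The map is then z-scored across all included units ("across the whole
brain") and averaged within each node at every scale. No detrending is
applied here: the pipeline assumes drift was removed upstream.
"""
from __future__ import annotations

import numpy as np

from .atlas import AtlasHierarchy
from .containers import AlffMap, NodeMetricVector, SubjectTimeseries
from .errors import ConfigurationError, DegenerateInputError, EmptyNodeError
from .simulate import DEFAULT_BAND


def compute_alff(ts: SubjectTimeseries,
                 band: tuple[float, float] = DEFAULT_BAND) -> AlffMap:
    """Per-unit sum of in-band single-sided DFT amplitudes."""
    low, high = band
    nyquist = 0.5 / ts.tr_seconds
    if not (0 < low < high <= nyquist):
        raise ConfigurationError(
            f"band must satisfy 0 < low < high <= Nyquist ({nyquist:g} Hz)")
    n = ts.n_timepoints
    freqs = np.fft.rfftfreq(n, d=ts.tr_seconds)
    sel = (freqs >= low) & (freqs <= high) & (freqs > 0)
    spec = np.fft.rfft(ts.data, axis=0)
    amplitudes = (2.0 / n) * np.abs(spec[sel, :])
    return AlffMap(values=amplitudes.sum(axis=0), unit_ids=ts.unit_ids,
                   band=(low, high), normalized=False,
                   subject_id=ts.subject_id, unit_labels=ts.unit_labels)


def zscore_map(m: AlffMap) -> AlffMap:
    """Standardise the map across units (sample sd, ddof=1)."""
    x = m.values
    if x.size < 2:
        raise DegenerateInputError("need at least 2 units to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero dispersion: all units share one value")
    return AlffMap(values=(x - x.mean()) / sd, unit_ids=m.unit_ids,
                   band=m.band, normalized=True, subject_id=m.subject_id,
                   unit_labels=m.unit_labels)


def node_average_alff(m: AlffMap, labels: np.ndarray, h: AtlasHierarchy,
                      scale: int) -> NodeMetricVector:
    """Unweighted mean of (z-scored) voxel ALFF within each node at ``scale``."""
    labels = np.asarray(labels)
    if labels.shape[0] != m.values.shape[0]:
        raise ValueError("labels must align with the map's units")
    coarse = h.coarsen_labels(labels.astype(int), scale)
    node_ids = h.node_ids(scale)
    names = dict(zip(node_ids, h.node_names(scale)))
    out = np.empty(len(node_ids))
    for j, nid in enumerate(node_ids):
        members = coarse == nid
        if not members.any():
            raise EmptyNodeError(
                f"parcel {names[int(nid)]} (id {int(nid)}, scale {scale}) has no voxels")
        out[j] = m.values[members].mean()
    return NodeMetricVector(metric_name="alff", values=out, node_ids=node_ids,
                            scale=scale, subject_id=m.subject_id)


def alff_node_metrics(ts: SubjectTimeseries, h: AtlasHierarchy,
                      band: tuple[float, float] = DEFAULT_BAND
                      ) -> list[NodeMetricVector]:
    """Voxel ALFF -> z-score -> node averages at every scale of ``h``."""
    if ts.unit_labels is None:
        raise ValueError("voxel-level series with unit_labels required")
    zmap = zscore_map(compute_alff(ts, band))
    return [node_average_alff(zmap, ts.unit_labels, h, s)
            for s in range(1, h.n_scales + 1)]


def save_alff_nifti(m: AlffMap, path) -> None:
    """Write a (units,1,1) ALFF volume as NIfTI."""
    import nibabel as nib

    vol = m.values.reshape(-1, 1, 1).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
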