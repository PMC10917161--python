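"""Hierarchical brain parcellation: a tree of parcels over several granularity scales.

Scale-1 is the finest parcellation and higher scales are progressively
coarser recombinations of the same parcels, so any finest-scale labelling
(of voxels or of graph nodes) can be mapped upward by table lookup. The
packaged gray-matter hierarchy has 84/58/16/6/4 nodes from Scale-1 to
Scale-5: gyrus-level structures recombine into lobes, lobes into cerebral
cortex vs. nuclei, and finally telencephalon vs. diencephalon, left and
right kept separate throughout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import MappingError, StructureError

_PACKAGED_TABLE = "gm_hierarchy_5scale.tsv"


@dataclass(frozen=True)
class AtlasHierarchy:
    """A validated multi-scale parcel tree.

    Parameters
    ----------
    parcels
        One list per scale (finest first) of ``(parcel_id, name)`` pairs, in
        canonical atlas order.
    parent
        One dict per scale mapping every finest-scale parcel id to its
        ancestor id at that scale. ``parent[0]`` is the identity.
    label_volume
        Optional 3-D integer array of finest-scale labels; 0 is background.
    """

    parcels: tuple
    parent: tuple
    label_volume: Optional[np.ndarray] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        _validate(self.parcels, self.parent)

    @property
    def n_scales(self) -> int:
        return len(self.parcels)

    def node_count(self, scale: int) -> int:
        """Number of parcels at ``scale`` (1 = finest)."""
        self._check_scale(scale)
        return len(self.parcels[scale - 1])

    def node_ids(self, scale: int) -> np.ndarray:
        """Parcel ids at ``scale`` in canonical atlas order."""
        self._check_scale(scale)
        return np.array([pid for pid, _ in self.parcels[scale - 1]])

    def node_names(self, scale: int) -> list[str]:
        self._check_scale(scale)
        return [name for _, name in self.parcels[scale - 1]]

    def ancestor(self, finest_id: int, scale: int) -> int:
        """Ancestor parcel id of a finest parcel at ``scale``."""
        self._check_scale(scale)
        try:
            return self.parent[scale - 1][int(finest_id)]
        except KeyError:
            raise MappingError(f"unknown finest parcel id {finest_id}") from None

    def coarsen_labels(self, finest_labels: np.ndarray, target_scale: int) -> np.ndarray:
        """Map an array of finest-scale labels to ``target_scale``; 0 passes through."""
        self._check_scale(target_scale)
        labels = np.asarray(finest_labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise MappingError("labels must be integers")
        lut = self.parent[target_scale - 1]
        nonzero = np.unique(labels[labels != 0])
        unknown = [int(v) for v in nonzero if int(v) not in lut]
        if unknown:
            raise MappingError(f"labels contain unknown finest parcel ids {unknown}")
        out = labels.copy()
        for v in nonzero:
            out[labels == v] = lut[int(v)]
        return out

    def children(self, scale: int, parcel_id: int) -> list[int]:
        """Finest-scale parcel ids descending from ``parcel_id`` at ``scale``."""
        self._check_scale(scale)
        return [fid for fid, anc in self.parent[scale - 1].items() if anc == parcel_id]

    def _check_scale(self, scale: int) -> None:
        if not 1 <= scale <= self.n_scales:
            raise IndexError(f"scale must be in 1..{self.n_scales}, got {scale}")


def _validate(parcels, parent) -> None:
    if len(parcels) != len(parent):
        raise StructureError("parcels and parent must have one entry per scale")
    if len(parcels) == 0:
        raise StructureError("hierarchy needs at least one scale")
    finest_ids = [pid for pid, _ in parcels[0]]
    for s, plist in enumerate(parcels, start=1):
        ids = [pid for pid, _ in plist]
        names = [name for _, name in plist]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate parcel ids at scale {s}")
        if len(set(names)) != len(names):
            raise StructureError(f"duplicate parcel names at scale {s}")
        if any(pid <= 0 for pid in ids):
            raise StructureError("parcel ids must be positive (0 is background)")
        pmap = parent[s - 1]
        missing = [fid for fid in finest_ids if fid not in pmap]
        if missing:
            raise MappingError(f"finest parcels {missing} lack an ancestor at scale {s}")
        targets = set(pmap.values())
        if targets != set(ids):
            orphans = set(ids) - targets
            alien = targets - set(ids)
            if alien:
                raise MappingError(f"scale {s} ancestors {sorted(alien)} are not parcels")
            raise MappingError(f"scale {s} parcels {sorted(orphans)} have no children")
    # Tree property: parcels sharing an ancestor at scale s also share one at s+1.
    for s in range(1, len(parcels)):
        groups: dict[int, set] = {}
        for fid in finest_ids:
            groups.setdefault(parent[s - 1][fid], set()).add(parent[s][fid])
        bad = {q: sorted(a) for q, a in groups.items() if len(a) > 1}
        if bad:
            raise StructureError(
                f"ancestry violation between scales {s} and {s + 1}: {bad}")


def load_hierarchy(lookup_table_path) -> AtlasHierarchy:
    """Read a hierarchy lookup table (TSV, one row per finest parcel).

    Expected columns: ``scale<k>_id`` and ``scale<k>_name`` for k = 1..S,
    Scale-1 being the finest. Parcel ids may repeat across rows at coarser
    scales (many finest parcels share an ancestor) but each id must pair
    with a single name.
    """
    table = pd.read_csv(lookup_table_path, sep="\t")
    scales = []
    k = 1
    while f"scale{k}_id" in table.columns:
        if f"scale{k}_name" not in table.columns:
            raise StructureError(f"scale{k}_name column missing")
        scales.append(k)
        k += 1
    if not scales:
        raise StructureError("no scale columns found in lookup table")

    parcels = []
    parent = []
    for s in scales:
        ids = table[f"scale{s}_id"].to_numpy()
        names = table[f"scale{s}_name"].astype(str).to_numpy()
        seen: dict[int, str] = {}
        order: list[int] = []
        for pid, name in zip(ids, names):
            pid = int(pid)
            if pid in seen:
                if seen[pid] != name:
                    raise StructureError(
                        f"scale {s} id {pid} maps to both '{seen[pid]}' and '{name}'")
            else:
                seen[pid] = name
                order.append(pid)
        name_to_ids: dict[str, set] = {}
        for pid, name in seen.items():
            name_to_ids.setdefault(name, set()).add(pid)
        dup = {n: sorted(v) for n, v in name_to_ids.items() if len(v) > 1}
        if dup:
            raise StructureError(f"scale {s} names used by multiple ids: {dup}")
        parcels.append(tuple((pid, seen[pid]) for pid in order))
        pmap = {int(f): int(a) for f, a in
                zip(table["scale1_id"].to_numpy(), ids)}
        parent.append(pmap)

    if len(table["scale1_id"].unique()) != len(table):
        raise StructureError("duplicate finest parcel rows in lookup table")
    return AtlasHierarchy(parcels=tuple(parcels), parent=tuple(parent))


def save_hierarchy(h: AtlasHierarchy, path) -> None:
    """Write a hierarchy as the TSV lookup table :func:`load_hierarchy` reads."""
    rows = []
    names = {s: dict(zip(h.node_ids(s), h.node_names(s)))
             for s in range(1, h.n_scales + 1)}
    for fid in h.node_ids(1):
        row = {}
        for s in range(1, h.n_scales + 1):
            anc = h.ancestor(int(fid), s)
            row[f"scale{s}_id"] = anc
            row[f"scale{s}_name"] = names[s][anc]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_default_hierarchy() -> AtlasHierarchy:
    """The packaged five-scale gray-matter hierarchy (84/58/16/6/4 nodes)."""
    ref = resources.files("netpyramid.data") / _PACKAGED_TABLE
    with resources.as_file(ref) as path:
        return load_hierarchy(path)


def load_label_volume(path) -> np.ndarray:
    """Read a NIfTI integer label volume (finest-scale parcels, 0 = background)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return np.rint(data).astype(np.int32)


def save_label_volume(labels: np.ndarray, path, affine: Optional[np.ndarray] = None) -> None:
    """Write an integer label volume as NIfTI."""
    import nibabel as nib

    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int32), affine)
    nib.save(img, str(path))


def export_scale_volumes(h: AtlasHierarchy, labels: np.ndarray, out_dir,
                         affine: Optional[np.ndarray] = None) -> list[Path]:
    """Write one coarsened label volume per scale; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(1, h.n_scales + 1):
        p = out_dir / f"labels_scale{s}.nii.gz"
        save_label_volume(h.coarsen_labels(labels, s), p, affine)
        paths.append(p)
    return paths
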