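"""Synthetic post-preprocessing BOLD cohorts with hierarchy-aligned covariance.

The generator emulates what the analysis assumes about preprocessed
resting-state data: TR = 2 s, 240 volumes (an 8-minute scan), signal power
confined to the 0.01-0.1 Hz band, and a modular covariance structure aligned
with the atlas tree. Each internal tree node at every scale carries an
independent band-limited latent signal; a voxel is a weighted sum of the
latents of its parcel and all coarser ancestors plus white noise, so
correlation between two voxels decreases as their lowest common ancestor
moves up the tree.

Band limitation is exact by construction: latents are synthesised in the
frequency domain with unit-variance support only on DFT bins inside the
band, which makes downstream spectral (ALFF) tests sharp.

Group effects are multiplicative reductions applied to designated finest
parcels in the patient group: ``coupling_reduction`` shrinks the ancestor
(shared) weights — lowering that node's correlation to the rest of the brain
— with the voxel signal rescaled to its original variance so the band
amplitude is unchanged; ``alff_reduction`` then scales the whole pre-noise
signal, lowering its band amplitude.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import signal as sp_signal

from .atlas import AtlasHierarchy
from .containers import SubjectTimeseries
from .errors import ConfigurationError, DegenerateInputError

DEFAULT_BAND = (0.01, 0.1)


@dataclass
class CohortDesign:
    """Specification of a synthetic two-group cohort.

    ``module_coupling`` gives the mixing weight of the ancestor latent at
    each coarser scale (length ``n_scales - 1``, scale 2 first); the parcel's
    own latent always enters with weight 1. Defaults follow a geometric
    decay, giving within-parcel voxel correlations near 0.65 and
    between-parcel correlations that fall off with tree distance — values in
    the range routinely seen in parcel-averaged resting-state data.
    """

    hierarchy: AtlasHierarchy
    n_patients: int = 21
    n_controls: int = 20
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    voxels_per_parcel: Union[int, Mapping[int, int]] = 10
    band: tuple[float, float] = DEFAULT_BAND
    module_coupling: Optional[Sequence[float]] = None
    effect_nodes: frozenset = frozenset()
    coupling_reduction: float = 0.0
    alff_reduction: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0 or self.n_timepoints <= 0:
            raise ConfigurationError("subject and timepoint counts must be positive")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        nyquist = 0.5 / self.tr_seconds
        low, high = self.band
        if not (0 < low < high <= nyquist):
            raise ConfigurationError(
                f"band must satisfy 0 < low < high <= Nyquist ({nyquist:g} Hz)")
        for name in ("coupling_reduction", "alff_reduction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.module_coupling is None:
            # weight 0.7^(s-1) for the ancestor at scale s
            self.module_coupling = tuple(
                0.7 ** s for s in range(1, self.hierarchy.n_scales))
        else:
            self.module_coupling = tuple(float(w) for w in self.module_coupling)
        if len(self.module_coupling) != self.hierarchy.n_scales - 1:
            raise ConfigurationError(
                "module_coupling needs one weight per coarser scale")
        self.effect_nodes = frozenset(int(p) for p in self.effect_nodes)
        known = set(int(i) for i in self.hierarchy.node_ids(1))
        if not self.effect_nodes <= known:
            raise ConfigurationError("effect_nodes must be finest-scale parcel ids")

    def parcel_voxel_count(self, parcel_id: int) -> int:
        if isinstance(self.voxels_per_parcel, Mapping):
            return int(self.voxels_per_parcel[parcel_id])
        return int(self.voxels_per_parcel)

    @property
    def signal_variance(self) -> float:
        """Pre-noise variance of a (non-effect) voxel: 1 + sum of squared weights."""
        return 1.0 + float(np.sum(np.square(self.module_coupling)))

    @property
    def within_parcel_correlation(self) -> float:
        """Implied correlation between two voxels of the same parcel."""
        v = self.signal_variance
        return v / (v + self.noise_sd ** 2)


def band_bins(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Indices of positive rfft bins whose frequency lies inside ``band`` (inclusive)."""
    freqs = np.fft.rfftfreq(n, d=tr)
    low, high = band
    return np.nonzero((freqs >= low) & (freqs <= high) & (freqs > 0))[0]


def band_limited_latent(rng: np.random.Generator, n: int, tr: float,
                        band: tuple[float, float]) -> np.ndarray:
    """Unit-variance signal with random phases on in-band DFT bins only."""
    bins = band_bins(n, tr, band)
    if bins.size == 0:
        raise ConfigurationError("band contains no DFT bins at this length/TR")
    amp = np.sqrt(2.0 / bins.size)          # K sinusoids of amplitude sqrt(2/K) -> var 1
    phases = rng.uniform(0.0, 2.0 * np.pi, size=bins.size)
    spec = np.zeros(n // 2 + 1, dtype=complex)
    spec[bins] = (n / 2.0) * amp * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n)


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """One independent, reproducible stream per (seed, subject_id)."""
    tag = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


def simulate_subject(design: CohortDesign, subject_id: str, group: str) -> SubjectTimeseries:
    """Generate one subject's voxel-level time series under the design."""
    h = design.hierarchy
    n, tr = design.n_timepoints, design.tr_seconds
    rng = _subject_rng(design.seed, subject_id)
    finest = [int(i) for i in h.node_ids(1)]

    # Latents per scale, keyed by parcel id at that scale, drawn in atlas order.
    latents: list[dict[int, np.ndarray]] = []
    for s in range(1, h.n_scales + 1):
        latents.append({int(pid): band_limited_latent(rng, n, tr, design.band)
                        for pid in h.node_ids(s)})

    w = np.asarray(design.module_coupling)
    full_var = design.signal_variance
    is_patient = group == "patient"

    cols, unit_ids, unit_labels = [], [], []
    voxel_counter = 0
    for pid in finest:
        sig = latents[0][pid].copy()
        weights = w.copy()
        if is_patient and pid in design.effect_nodes and design.coupling_reduction > 0:
            weights = weights * (1.0 - design.coupling_reduction)
        for s in range(2, h.n_scales + 1):
            sig += weights[s - 2] * latents[s - 1][h.ancestor(pid, s)]
        if is_patient and pid in design.effect_nodes:
            if design.coupling_reduction > 0:
                red_var = 1.0 + float(np.sum(weights ** 2))
                sig *= np.sqrt(full_var / red_var)   # keep amplitude unchanged
            sig *= (1.0 - design.alff_reduction)
        n_vox = design.parcel_voxel_count(pid)
        noise = rng.normal(0.0, design.noise_sd, size=(n, n_vox))
        cols.append(sig[:, None] + noise)
        unit_ids.extend(range(voxel_counter, voxel_counter + n_vox))
        unit_labels.extend([pid] * n_vox)
        voxel_counter += n_vox

    return SubjectTimeseries(
        data=np.concatenate(cols, axis=1),
        tr_seconds=tr,
        unit_ids=np.array(unit_ids),
        subject_id=subject_id,
        group=group,
        unit_labels=np.array(unit_labels),
    )


def generate_cohort(design: CohortDesign) -> list[SubjectTimeseries]:
    """Generate the full cohort, patients first then controls.

    Subjects are independent given the design; each draws from its own RNG
    stream derived from (seed, subject_id), so the cohort is bit-reproducible
    regardless of generation order.
    """
    subjects = []
    for i in range(design.n_patients):
        subjects.append(simulate_subject(design, f"patient_{i + 1:03d}", "patient"))
    for i in range(design.n_controls):
        subjects.append(simulate_subject(design, f"control_{i + 1:03d}", "control"))
    return subjects


def band_power_fraction(ts: np.ndarray, tr_seconds: float,
                        band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Fraction of total non-DC periodogram power inside ``band`` (inclusive)."""
    x = np.asarray(ts, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("expected a 1-D series of length >= 4")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no defined band power fraction")
    freqs, pxx = sp_signal.periodogram(x, fs=1.0 / tr_seconds, detrend=False)
    pxx = pxx[freqs > 0]
    freqs = freqs[freqs > 0]
    total = pxx.sum()
    if total == 0:
        raise DegenerateInputError("series has no non-DC power")
    low, high = band
    return float(pxx[(freqs >= low) & (freqs <= high)].sum() / total)


# ---------------------------------------------------------------------------
# Cohort I/O: TSV tables (one per subject + manifest) and NIfTI 4D export.

def write_cohort_tsv(subjects: Sequence[SubjectTimeseries], out_dir) -> Path:
    """Write per-subject time x unit TSVs, a labels table, and a manifest."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in subjects:
        fname = f"{ts.subject_id}.tsv"
        pd.DataFrame(ts.data, columns=[str(u) for u in ts.unit_ids]).to_csv(
            out_dir / fname, sep="\t", index=False, float_format="%.6g")
        rows.append({"subject_id": ts.subject_id, "group": ts.group,
                     "file": fname, "tr_seconds": ts.tr_seconds})
    first = subjects[0]
    if first.unit_labels is not None:
        pd.DataFrame({"unit_id": first.unit_ids,
                      "finest_parcel": first.unit_labels}).to_csv(
            out_dir / "unit_labels.tsv", sep="\t", index=False)
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort_tsv(manifest_path) -> list[SubjectTimeseries]:
    """Read a cohort written by :func:`write_cohort_tsv`."""
    import pandas as pd

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    labels_file = root / "unit_labels.tsv"
    unit_labels = None
    if labels_file.exists():
        lab = pd.read_csv(labels_file, sep="\t")
        unit_labels = lab["finest_parcel"].to_numpy()
    subjects = []
    for row in manifest.itertuples():
        df = pd.read_csv(root / row.file, sep="\t")
        subjects.append(SubjectTimeseries(
            data=df.to_numpy(),
            tr_seconds=float(row.tr_seconds),
            unit_ids=np.array([int(c) for c in df.columns]),
            subject_id=str(row.subject_id),
            group=str(row.group),
            unit_labels=unit_labels,
        ))
    return subjects


def subject_to_nifti(ts: SubjectTimeseries, bold_path, labels_path=None) -> None:
    """Write a subject as a 4D NIfTI (units laid out along x) plus label volume."""
    import nibabel as nib

    data4d = ts.data.T.reshape(ts.n_units, 1, 1, ts.n_timepoints)
    affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data4d, dtype=np.float32), affine)
    img.header.set_zooms((1.0, 1.0, 1.0, ts.tr_seconds))
    nib.save(img, str(bold_path))
    if labels_path is not None and ts.unit_labels is not None:
        lab = ts.unit_labels.reshape(ts.n_units, 1, 1).astype(np.int32)
        nib.save(nib.Nifti1Image(lab, affine), str(labels_path))


def subject_from_nifti(bold_path, labels_path, subject_id: str, group: str,
                       tr_seconds: Optional[float] = None) -> SubjectTimeseries:
    """Read a 4D BOLD NIfTI and its finest-scale label volume into a voxel series."""
    import nibabel as nib

    img = nib.load(str(bold_path))
    data4d = np.asanyarray(img.dataobj, dtype=float)
    labels = np.rint(np.asanyarray(nib.load(str(labels_path)).dataobj)).astype(int)
    if tr_seconds is None:
        tr_seconds = float(img.header.get_zooms()[3])
    mask = labels > 0
    data = data4d[mask].T                      # (time, voxels in mask)
    return SubjectTimeseries(
        data=data, tr_seconds=tr_seconds,
        unit_ids=np.arange(int(mask.sum())),
        subject_id=subject_id, group=group,
        unit_labels=labels[mask],
    )
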