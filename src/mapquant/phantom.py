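"""Synthetic mpMRI exam generator with known ground truth.

Builds a schematic liver phantom: an ellipsoid partitioned into the nine
Couinaud-style units (a central caudate-like cylinder plus four angular
wedges per axial half) with two tubular vessel trees, rendered as

* a thin-slice anatomical source volume (Dixon-in-phase-like, 3 mm slices),
* an integer label map on the source grid,
* sparse parametric map volumes (4 axial slices, 8 mm thick, 20-32 mm
  apart) whose voxels carry per-segment ground-truth relaxation times in
  milliseconds plus configurable Gaussian noise,

all sharing one world coordinate frame.  The geometry is deliberately
schematic: nothing downstream depends on anatomical realism, only on
labels, affines and values.  Ground-truth values follow the physiological
ranges of liver relaxometry (noncontrast T1 around 835 ms, post-contrast T1
around 518 ms, T2 around 37 ms).

Artifact plumbing covers the disturbances the QC chain is designed to
catch: speckle outliers, full-range-noise segments, and breathing motion
(a world-z shift of the source affine that the NCC slice subselection must
undo).  A shared smooth intensity modulation ("texture") can be enabled so
that map and source slices carry correlated anatomy, which is what NCC
needs; it is off by default so that noiseless maps equal their ground truth
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import (
    LABEL_SCHEME,
    LabelMap,
    SEGMENT_NAMES,
    Volume,
    write_label_map,
    write_volume,
)

__all__ = ["PhantomSpec", "PhantomExam", "generate_phantom", "inject_breathing_shift", "write_exam"]

#: nominal intensity ranges of the map sequences (12-bit; T2 at 0.1 ms steps)
SEQUENCE_INTENSITY_RANGES = {
    "t1_pre": (0.0, 4095.0),
    "t1_post": (0.0, 4095.0),
    "t2": (0.0, 409.5),
}

#: blood-pool values rendered inside vessels, per sequence (ms)
BLOOD_VALUES = {"t1_pre": 1600.0, "t1_post": 300.0, "t2": 180.0}

_UPPER_WEDGES = ("II", "IVa", "VII", "VIII")
_LOWER_WEDGES = ("III", "IVb", "V", "VI")


@dataclass
class PhantomSpec:
    """Generator parameters; the defaults emulate a typical liver mpMRI
    acquisition (thin-slice source, four sparse map slices) and
    physiological value ranges."""

    seed: int = 0
    # source (anatomical) geometry
    source_shape: tuple[int, int, int] = (96, 96, 80)
    source_pixel_spacing: float = 1.25
    source_slice_spacing: float = 3.0
    source_slice_thickness: float = 3.0
    # parametric map geometry
    map_shape: tuple[int, int, int] = (64, 64, 4)
    map_pixel_spacing: float = 2.08
    map_slice_spacing: float = 32.0
    map_slice_thickness: float = 8.0
    sequences: tuple[str, ...] = ("t1_pre", "t1_post", "t2")
    # ground-truth value model (ms): one exam-level (between-patient) draw
    # N(mean, sd^2) per sequence, plus small within-liver per-segment
    # offsets N(0, segment_sd^2) — segmental relaxation times within one
    # liver vary far less than they do across patients
    value_means: dict = field(default_factory=lambda: {"t1_pre": 835.0, "t1_post": 518.0, "t2": 37.0})
    value_sds: dict = field(default_factory=lambda: {"t1_pre": 50.0, "t1_post": 30.0, "t2": 4.0})
    segment_sds: dict = field(default_factory=lambda: {"t1_pre": 5.0, "t1_post": 3.0, "t2": 0.3})
    # noise and artifacts
    noise_sigma_frac: float = 0.02  # Gaussian sigma as fraction of the local true value
    texture_amp: float = 0.0  # shared map/source anatomical modulation (fraction)
    outlier_fraction: float = 0.0  # fraction of liver map voxels turned into speckle spikes
    high_noise_segments: tuple[str, ...] = ()  # segments rendered as full-range noise
    # synthetic reader noise for the manual table (ms)
    reader_sigma: dict = field(default_factory=lambda: {"t1_pre": 5.0, "t1_post": 5.0, "t2": 1.0})
    # anatomy
    liver_semiaxes: tuple[float, float, float] = (46.0, 38.0, 80.0)  # mm
    segment_i_radius: float = 10.0  # mm, central cylinder
    vessel_radius: float = 4.0  # mm
    source_liver_intensity: float = 400.0
    source_background_intensity: float = 40.0
    source_vessel_intensity: float = 700.0

    def __post_init__(self) -> None:
        for v in (self.source_pixel_spacing, self.source_slice_spacing,
                  self.map_pixel_spacing, self.map_slice_spacing):
            if v <= 0:
                raise ValueError("all spacings must be positive")
        for seq in self.sequences:
            if self.value_means[seq] <= 0:
                raise ValueError("ground-truth values must be positive")


@dataclass
class PhantomExam:
    """A generated exam: volumes, ground-truth manifest and synthetic
    manual readings."""

    exam_id: str
    source: Volume
    labels: LabelMap
    maps: list[Volume]
    manifest: pd.DataFrame  # segment, sequence_id, true_value_ms
    manual: pd.DataFrame  # exam_id, sequence_id, segment, value_ms
    meta: dict = field(default_factory=dict)

    def truth(self, segment: str, sequence_id: str) -> float:
        row = self.manifest[
            (self.manifest.segment == segment) & (self.manifest.sequence_id == sequence_id)
        ]
        return float(row.true_value_ms.iloc[0])


# -- geometry ---------------------------------------------------------------

def _centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(liver centre world point, source affine, map affine)."""
    ps, ss = spec.source_pixel_spacing, spec.source_slice_spacing
    src_affine = np.diag([ps, ps, ss, 1.0])
    nx, ny, nz = spec.source_shape
    center = np.array([(nx - 1) / 2 * ps, (ny - 1) / 2 * ps, (nz - 1) / 2 * ss])
    mps, mss = spec.map_pixel_spacing, spec.map_slice_spacing
    mx, my, mz = spec.map_shape
    map_affine = np.diag([mps, mps, mss, 1.0])
    map_affine[0, 3] = center[0] - (mx - 1) / 2 * mps
    map_affine[1, 3] = center[1] - (my - 1) / 2 * mps
    map_affine[2, 3] = center[2] - (mz - 1) / 2 * mss
    return center, src_affine, map_affine


def segment_field(points: np.ndarray, spec: PhantomSpec, center: np.ndarray) -> np.ndarray:
    """Ground-truth label of arbitrary world points, shape (N, 3) -> (N,).

    The analytic phantom definition: ellipsoidal liver, central cylinder =
    segment I, four angular wedges per axial half, vessel tubes overriding
    parenchyma.  This is the single source of truth used both to rasterize
    the label map and to render the parametric maps.
    """
    d = points - center[None, :]
    a, b, c = spec.liver_semiaxes
    inside = (d[:, 0] / a) ** 2 + (d[:, 1] / b) ** 2 + (d[:, 2] / c) ** 2 <= 1.0
    labels = np.zeros(points.shape[0], dtype=np.int16)
    if not inside.any():
        return labels
    dx, dy, dz = d[inside, 0], d[inside, 1], d[inside, 2]
    seg = np.empty(dx.shape, dtype=np.int16)
    upper = dz >= 0
    theta = np.arctan2(dy, dx)  # [-pi, pi)
    quad = np.clip(((theta + np.pi) / (np.pi / 2)).astype(int), 0, 3)
    name_to_label = {v: k for k, v in LABEL_SCHEME.items()}
    for q in range(4):
        seg[upper & (quad == q)] = name_to_label[_UPPER_WEDGES[q]]
        seg[~upper & (quad == q)] = name_to_label[_LOWER_WEDGES[q]]
    # caudate-like central cylinder through both halves
    central = dx**2 + dy**2 <= spec.segment_i_radius**2
    seg[central] = name_to_label["I"]
    # vessels override parenchyma: a portal tube along x and two hepatic
    # tubes along z, entirely inside the ellipsoid by construction
    r = spec.vessel_radius
    portal = (dy**2 + (dz + 8.0) ** 2) <= r**2
    hepatic = ((dx - 20.0) ** 2 + (dy - 8.0) ** 2 <= (0.9 * r) ** 2) | (
        (dx + 20.0) ** 2 + (dy - 8.0) ** 2 <= (0.9 * r) ** 2
    )
    seg[portal] = name_to_label["portal_vessels"]
    seg[hepatic & ~portal] = name_to_label["hepatic_vessels"]
    labels[inside] = seg
    return labels


def _grid_world(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    return (affine @ idx)[:3].T  # (N, 3)


def _texture(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Smooth zero-mean anatomical modulation shared by source and maps.

    The in-plane pattern translates with world z (wavelength ~60 mm in
    plane, ~19 mm through-plane), so slices a few mm apart are partially
    decorrelated — the property breathing-motion NCC recovery relies on.
    """
    d = points - center[None, :]
    x, y, z = d[:, 0], d[:, 1], d[:, 2]
    # several incommensurate components so the in-plane pattern's
    # autocorrelation across z peaks sharply at zero lag
    t = (
        np.sin(x / 10.0 + z / 3.0) * np.cos(y / 12.0 + z / 5.0)
        + np.cos(x / 14.0 - z / 4.0) * np.sin(y / 9.0 - z / 6.0)
        + np.sin(x / 7.0 - y / 11.0 + z / 3.5)
    )
    return t / 3.0


# -- generation -------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> PhantomExam:
    """Deterministically generate one synthetic exam from a spec."""
    rng = np.random.default_rng(spec.seed)
    exam_id = f"phantom{spec.seed:05d}"
    center, src_affine, map_affine = _centers(spec)
    name_to_label = {v: k for k, v in LABEL_SCHEME.items()}

    # ground-truth relaxation times per segment and sequence
    truths: dict[str, dict[str, float]] = {}
    for seq in spec.sequences:
        mu, sd = spec.value_means[seq], spec.value_sds[seq]
        exam_level = rng.normal(mu, sd)
        offsets = rng.normal(0.0, spec.segment_sds.get(seq, 0.0), size=len(SEGMENT_NAMES))
        draw = np.maximum(exam_level + offsets, 0.2 * mu)  # keep strictly positive
        truths[seq] = {seg: float(v) for seg, v in zip(SEGMENT_NAMES, draw)}

    # label map on the source grid
    src_points = _grid_world(spec.source_shape, src_affine)
    src_labels = segment_field(src_points, spec, center).reshape(spec.source_shape)
    labels = LabelMap(
        data=src_labels, affine=src_affine.copy(), sequence_id="labels",
        slice_thickness=spec.source_slice_thickness,
    )

    # anatomical source volume
    tex_src = _texture(src_points, center).reshape(spec.source_shape)
    src = np.full(spec.source_shape, spec.source_background_intensity)
    parenchyma = (src_labels >= name_to_label["I"]) & (src_labels <= name_to_label["VIII"])
    vessels = src_labels >= name_to_label["portal_vessels"]
    src = np.where(parenchyma, spec.source_liver_intensity, src)
    src = np.where(vessels, spec.source_vessel_intensity, src)
    src = src * (1.0 + 4.0 * spec.texture_amp * tex_src * (parenchyma | vessels))
    if spec.noise_sigma_frac > 0:
        src = src + rng.normal(0.0, spec.noise_sigma_frac * np.abs(src))
    source = Volume(
        data=src, affine=src_affine.copy(), sequence_id="dixon_ip",
        slice_thickness=spec.source_slice_thickness,
        intensity_range=(0.0, 2028.0),
    )

    # parametric maps
    map_points = _grid_world(spec.map_shape, map_affine)
    map_seg = segment_field(map_points, spec, center)
    tex_map = _texture(map_points, center)
    maps: list[Volume] = []
    missing: list[str] = []
    for seq in spec.sequences:
        base = np.zeros(map_seg.shape[0])
        for seg_name in SEGMENT_NAMES:
            base[map_seg == name_to_label[seg_name]] = truths[seq][seg_name]
        base[map_seg == name_to_label["portal_vessels"]] = BLOOD_VALUES.get(seq, 200.0)
        base[map_seg == name_to_label["hepatic_vessels"]] = BLOOD_VALUES.get(seq, 200.0)
        vals = base * (1.0 + spec.texture_amp * tex_map)
        if spec.noise_sigma_frac > 0:
            vals = vals + rng.normal(0.0, spec.noise_sigma_frac * np.abs(base))
        lo, hi = SEQUENCE_INTENSITY_RANGES.get(seq, (0.0, 4095.0))
        for seg_name in spec.high_noise_segments:
            sel = map_seg == name_to_label[seg_name]
            vals[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
        if spec.outlier_fraction > 0:
            liver = (map_seg >= name_to_label["I"]) & (map_seg <= name_to_label["VIII"])
            liver_idx = np.flatnonzero(liver)
            n_spike = int(round(spec.outlier_fraction * liver_idx.size))
            if n_spike:
                pick = rng.choice(liver_idx, size=n_spike, replace=False)
                vals[pick] = vals[pick] * rng.uniform(1.8, 2.5, size=n_spike)
        maps.append(Volume(
            data=vals.reshape(spec.map_shape), affine=map_affine.copy(),
            sequence_id=seq, slice_thickness=spec.map_slice_thickness,
            intensity_range=(lo, hi),
        ))

    # warn on segments invisible to the maps (useful for omission tests)
    for seg_name in SEGMENT_NAMES:
        if not np.any(map_seg == name_to_label[seg_name]):
            missing.append(seg_name)
    if missing:
        warnings.warn(f"segments with zero voxels on all map slices: {missing}", stacklevel=2)

    manifest = pd.DataFrame(
        [
            {"segment": seg, "sequence_id": seq, "true_value_ms": truths[seq][seg]}
            for seq in spec.sequences
            for seg in SEGMENT_NAMES
        ]
    )
    manual = manifest.rename(columns={"true_value_ms": "value_ms"}).copy()
    manual["value_ms"] = [
        truths[row.sequence_id][row.segment]
        + rng.normal(0.0, spec.reader_sigma.get(row.sequence_id, 5.0))
        for row in manual.itertuples()
    ]
    manual.insert(0, "exam_id", exam_id)

    return PhantomExam(
        exam_id=exam_id, source=source, labels=labels, maps=maps,
        manifest=manifest, manual=manual,
        meta={"seed": spec.seed, "breathing_shift_mm": 0.0},
    )


def inject_breathing_shift(exam: PhantomExam, shift_mm: float) -> PhantomExam:
    """Simulate breathing between acquisitions.

    The source (and label) affine is translated by ``shift_mm`` along world
    z while the maps stay put: the anatomy in the source arrays no longer
    sits where its affine claims relative to the maps, which is exactly the
    misalignment NCC source-slice subselection is meant to recover.
    """
    src_extent = exam.source.n_slices * exam.source.slice_spacing
    if abs(shift_mm) >= src_extent:
        raise ValueError("shift exceeds the source stack extent")
    if shift_mm == 0:
        return exam
    shifted_src_aff = exam.source.affine.copy()
    shifted_src_aff[2, 3] += shift_mm
    shifted_lab_aff = exam.labels.affine.copy()
    shifted_lab_aff[2, 3] += shift_mm
    meta = dict(exam.meta)
    meta["breathing_shift_mm"] = meta.get("breathing_shift_mm", 0.0) + shift_mm
    return replace(
        exam,
        source=exam.source.with_affine(shifted_src_aff),
        labels=replace(exam.labels, affine=shifted_lab_aff),
        meta=meta,
    )


def write_exam(exam: PhantomExam, out_dir: str | Path) -> Path:
    """Write an exam to a directory: NIfTI volumes, sidecar label scheme,
    ground-truth manifest and synthetic manual readings (CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(exam.source, out / "dixon_ip.nii.gz")
    write_label_map(exam.labels, out / "labels.nii.gz")
    for m in exam.maps:
        write_volume(m, out / f"{m.sequence_id}.nii.gz")
    exam.manifest.to_csv(out / "manifest.csv", index=False)
    exam.manual.to_csv(out / "manual.csv", index=False)
    return out
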