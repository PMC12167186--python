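"""NIfTI volume I/O and affine geometry.

The whole pipeline works in the scanner's physical coordinate frame: every
volume carries the 4x4 voxel-index -> world-mm affine from its NIfTI header,
and volumes acquired in the same session are related purely through these
matrices (no image registration is estimated).  This module provides the
:class:`Volume` / :class:`LabelMap` containers, voxel<->world mapping, and
the Euclidean nearest-neighbor slice correspondence between a thin-slice
anatomical stack and a sparse parametric map.

Conventions
-----------
* Arrays are indexed ``(i, j, k)`` with ``k`` the slice (through-plane) axis;
  voxel indices are 0-based.
* The world frame is whatever the NIfTI affine encodes (RAS-style for
  conformant files); no reorientation is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelMap",
    "SliceCorrespondence",
    "LABEL_SCHEME",
    "SEGMENT_NAMES",
    "VESSEL_NAMES",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "voxel_to_world",
    "world_to_voxel",
    "slice_center_world",
    "match_slices",
]

#: Canonical 12-category label scheme: background, the nine Couinaud
#: segments (IV split into IVa/IVb), and the two vessel trees.
LABEL_SCHEME: dict[int, str] = {
    0: "background",
    1: "I",
    2: "II",
    3: "III",
    4: "IVa",
    5: "IVb",
    6: "V",
    7: "VI",
    8: "VII",
    9: "VIII",
    10: "portal_vessels",
    11: "hepatic_vessels",
}

SEGMENT_NAMES: tuple[str, ...] = ("I", "II", "III", "IVa", "IVb", "V", "VI", "VII", "VIII")
VESSEL_NAMES: tuple[str, ...] = ("portal_vessels", "hepatic_vessels")


@dataclass
class Volume:
    """A 3-D scalar image with its voxel->world affine and acquisition tags.

    Parameters
    ----------
    data:
        3-D array, shape ``(nx, ny, n_slices)``.  Intensities are arbitrary
        units for anatomical volumes and milliseconds for relaxation maps.
    affine:
        4x4 invertible matrix mapping homogeneous 0-based voxel indices to
        world millimetres.
    sequence_id:
        Free-text acquisition tag, e.g. ``"t1_pre"``, ``"t2"``, ``"dixon_ip"``.
    slice_thickness:
        Excitation slab thickness in mm (metadata only; defaults to the
        centre-to-centre slice spacing).
    intensity_range:
        The sequence's nominal intensity range ``(lo, hi)``, used by the
        histogram-entropy QC gate.
    """

    data: np.ndarray
    affine: np.ndarray
    sequence_id: str = ""
    slice_thickness: float | None = None
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume payload must be 3-D, got {self.data.ndim}-D shape {self.data.shape}"
            )
        if self.data.shape[2] < 1:
            raise ValueError("volume must contain at least one slice")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("non-invertible affine")
        if self.slice_thickness is None:
            self.slice_thickness = self.slice_spacing

    # -- derived geometry ---------------------------------------------------
    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    @property
    def pixel_spacing(self) -> tuple[float, float]:
        """In-plane (row, col) spacing in mm (norms of the first two affine columns)."""
        return (
            float(np.linalg.norm(self.affine[:3, 0])),
            float(np.linalg.norm(self.affine[:3, 1])),
        )

    @property
    def slice_spacing(self) -> float:
        """Centre-to-centre spacing between consecutive slices in mm."""
        return float(np.linalg.norm(self.affine[:3, 2]))

    def with_affine(self, affine: np.ndarray) -> "Volume":
        return replace(self, affine=np.asarray(affine, dtype=float))


@dataclass
class LabelMap(Volume):
    """Integer category image sharing :class:`Volume` geometry.

    ``scheme`` maps label integer -> category name; every nonzero label in
    ``data`` must be declared.  Background is label 0.
    """

    scheme: dict[int, str] = field(default_factory=lambda: dict(LABEL_SCHEME))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map data must be integer-typed")
        present = set(np.unique(self.data).tolist())
        if len(present) > 12:
            raise ValueError(f"label map has {len(present)} distinct labels, scheme allows 12")
        undeclared = present - set(self.scheme) - {0}
        if undeclared:
            raise ValueError(f"labels {sorted(undeclared)} not in declared scheme")

    def label_of(self, name: str) -> int:
        for k, v in self.scheme.items():
            if v == name:
                return k
        raise KeyError(name)


@dataclass
class SliceCorrespondence:
    """Per-map-slice nearest source slice, with the world distance in mm."""

    entries: list[tuple[int, int, float]]

    def source_index(self, map_slice: int) -> int:
        for m, s, _ in self.entries:
            if m == map_slice:
                return s
        raise KeyError(map_slice)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# -- file I/O ---------------------------------------------------------------

def read_volume(path: str | Path, sequence_id: str = "",
                intensity_range: tuple[float, float] | None = None) -> Volume:
    """Read a NIfTI-1 volume.

    The file's affine is carried verbatim; intensities are returned with the
    standard NIfTI ``scl_slope``/``scl_inter`` scaling applied and nothing
    else.  Raises distinct errors for a missing file, a non-3D payload and a
    degenerate affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: volume payload must be 3-D, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError(f"{path}: non-invertible affine")
    return Volume(data=data, affine=affine, sequence_id=sequence_id,
                  intensity_range=intensity_range)


def write_volume(vol: Volume, path: str | Path, dtype=np.float32) -> Path:
    """Write a volume as NIfTI-1 (``.nii`` or ``.nii.gz`` by extension)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header.set_data_dtype(dtype)
    nib.save(img, str(path))
    return path


def read_label_map(path: str | Path, scheme_path: str | Path | None = None) -> LabelMap:
    """Read an integer label map plus its sidecar JSON label scheme.

    ``scheme_path`` defaults to ``<path minus .nii/.nii.gz>.labels.json``;
    if no sidecar exists the canonical 12-category scheme is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label map file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.rint(data).astype(np.int16)
    scheme = dict(LABEL_SCHEME)
    if scheme_path is None:
        base = str(path)
        for suf in (".nii.gz", ".nii"):
            if base.endswith(suf):
                base = base[: -len(suf)]
                break
        candidate = Path(base + ".labels.json")
        scheme_path = candidate if candidate.exists() else None
    if scheme_path is not None:
        with open(scheme_path) as fh:
            scheme = {int(k): str(v) for k, v in json.load(fh).items()}
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError(f"{path}: non-invertible affine")
    return LabelMap(data=data, affine=affine, sequence_id="labels", scheme=scheme)


def write_label_map(labels: LabelMap, path: str | Path) -> Path:
    """Write a label map (int16) and its sidecar ``.labels.json`` scheme."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(labels.data, dtype=np.int16), labels.affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))
    base = str(path)
    for suf in (".nii.gz", ".nii"):
        if base.endswith(suf):
            base = base[: -len(suf)]
            break
    with open(base + ".labels.json", "w") as fh:
        json.dump({str(k): v for k, v in labels.scheme.items()}, fh, indent=1)
    return path


# -- coordinate mapping -----------------------------------------------------

def voxel_to_world(vol: Volume, index: Sequence[float]) -> np.ndarray:
    """Map a voxel index triple to world mm: ``affine @ (i, j, k, 1)``.

    Integer indices are bounds-checked; fractional indices are allowed for
    interpolation use and are not.
    """
    idx = np.asarray(index, dtype=float)
    if idx.shape != (3,):
        raise ValueError("index must be a triple")
    if np.all(idx == np.rint(idx)):
        ii = np.rint(idx).astype(int)
        if np.any(ii < 0) or np.any(ii >= np.asarray(vol.data.shape)):
            raise IndexError(f"voxel index {tuple(ii)} out of bounds for shape {vol.data.shape}")
    return (vol.affine @ np.append(idx, 1.0))[:3]


def world_to_voxel(vol: Volume, point: Sequence[float]) -> np.ndarray:
    """Map a world-mm point to the (continuous) voxel index triple."""
    pt = np.asarray(point, dtype=float)
    if pt.shape != (3,):
        raise ValueError("point must be a triple")
    inv = np.linalg.inv(vol.affine)
    return (inv @ np.append(pt, 1.0))[:3]


def slice_center_world(vol: Volume, k: int) -> np.ndarray:
    """World position of slice ``k``'s in-plane central voxel index.

    The centre is the image of ``((nx-1)/2, (ny-1)/2, k)`` under the affine,
    which stays meaningful for oblique acquisitions where the world z
    coordinate alone would not identify a slice.
    """
    nx, ny, _ = vol.data.shape
    idx = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, float(k), 1.0])
    return (vol.affine @ idx)[:3]


def match_slices(map_vol: Volume, source_vol: Volume) -> SliceCorrespondence:
    """Euclidean nearest-neighbor slice correspondence map -> source.

    For every map slice the source slice whose world-space centre point is
    closest (Euclidean distance in mm) is selected; ties break toward the
    lower source index.  Map slices whose centres fall beyond the source
    stack are clamped to the terminal slice, with the (positive) distance
    recorded so callers can flag the extrapolation.
    """
    if source_vol.n_slices < 1:
        raise ValueError("source volume has no slices")
    src_centers = np.stack([slice_center_world(source_vol, k)
                            for k in range(source_vol.n_slices)])
    entries: list[tuple[int, int, float]] = []
    for m in range(map_vol.n_slices):
        c = slice_center_world(map_vol, m)
        d = np.linalg.norm(src_centers - c[None, :], axis=1)
        # argmin returns the first (lowest-index) minimizer, our tie-break
        s = int(np.argmin(np.round(d, 9)))
        entries.append((m, s, float(d[s])))
    return SliceCorrespondence(entries=entries)
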