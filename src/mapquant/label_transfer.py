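"""Transfer of segmental labels onto parametric map grids.

Labels live on the thin-slice anatomical (Dixon in-phase) grid; relaxation
maps are acquired on much coarser grids in the same scanner coordinate
frame.  Each map voxel is carried to world mm through the map affine and
then into the label volume through the inverse source affine; the label is
looked up with nearest-neighbor interpolation (labels are categorical, any
averaging would be meaningless).

Two lookup modes exist:

``slice`` (default)
    The through-plane coordinate is pinned to the matched source slice from
    :func:`mapquant.volume_io.match_slices` (optionally overridden per slice
    after NCC subselection), and the nearest voxel is found in-plane within
    that slice.  This mirrors a per-map-slice quantification design where
    each map slice is paired with exactly one source slice.

``3d``
    The nearest source voxel in all three axes; offered for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume_io import LabelMap, SliceCorrespondence, Volume, SEGMENT_NAMES

__all__ = ["ROIMask", "transfer_label_grid", "transfer_labels", "transfer_segment_slice"]

#: sentinel used in transferred grids for map voxels whose world point falls
#: outside the source field of view ("no ROI"); background (0) also yields
#: no ROI but is kept distinct for bookkeeping.
OUT_OF_FIELD = -1


@dataclass
class ROIMask:
    """Boolean ROI of one segment on one parametric map volume."""

    segment: str
    map_sequence_id: str
    mask: np.ndarray  # bool, congruent with the map volume
    source_slice_used: list[int]  # per map slice, after any subselection

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def per_slice_counts(self) -> list[int]:
        return [int(self.mask[:, :, k].sum()) for k in range(self.mask.shape[2])]


def _inplane_world_grid(map_vol: Volume, k: int) -> np.ndarray:
    """Homogeneous world coordinates of every voxel centre on map slice k, shape (4, N)."""
    nx, ny, _ = map_vol.data.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    idx = np.stack(
        [ii.ravel(), jj.ravel(), np.full(ii.size, float(k)), np.ones(ii.size)]
    )
    return map_vol.affine @ idx


def transfer_label_grid(
    labels: LabelMap,
    map_vol: Volume,
    correspondence: SliceCorrespondence,
    mode: str = "slice",
) -> np.ndarray:
    """Resample the label volume onto the map grid.

    Returns an integer array congruent with ``map_vol.data`` holding the
    transferred label of every map voxel, or :data:`OUT_OF_FIELD` where the
    voxel's world point has no nearest source voxel inside the field of
    view.  In ``slice`` mode the through-plane lookup is fixed to the
    matched source slice for that map slice.
    """
    if mode not in ("slice", "3d"):
        raise ValueError(f"unknown transfer mode {mode!r}")
    inv_src = np.linalg.inv(labels.affine)
    snx, sny, snz = labels.data.shape
    nx, ny, nz = map_vol.data.shape
    out = np.full((nx, ny, nz), OUT_OF_FIELD, dtype=np.int16)
    for m, s, _dist in correspondence:
        world = _inplane_world_grid(map_vol, m)
        vox = inv_src @ world
        si = np.rint(vox[0]).astype(int)
        sj = np.rint(vox[1]).astype(int)
        if mode == "slice":
            sk = np.full(si.shape, s)
            in_field = (si >= 0) & (si < snx) & (sj >= 0) & (sj < sny)
        else:
            sk = np.rint(vox[2]).astype(int)
            in_field = (
                (si >= 0) & (si < snx)
                & (sj >= 0) & (sj < sny)
                & (sk >= 0) & (sk < snz)
            )
        lab = np.full(si.shape, OUT_OF_FIELD, dtype=np.int16)
        lab[in_field] = labels.data[si[in_field], sj[in_field], sk[in_field]]
        out[:, :, m] = lab.reshape(nx, ny)
    if not np.any(out > 0):
        warnings.warn(
            "label transfer produced no foreground voxels (disjoint world extents?)",
            stacklevel=2,
        )
    return out


def transfer_segment_slice(
    labels: LabelMap,
    map_vol: Volume,
    map_slice: int,
    source_slice: int,
    label_value: int,
) -> np.ndarray:
    """2-D mask of one segment on one map slice, looked up in one source slice.

    Used to re-transfer a single slice after NCC source-slice subselection.
    """
    inv_src = np.linalg.inv(labels.affine)
    snx, sny, _ = labels.data.shape
    nx, ny, _ = map_vol.data.shape
    world = _inplane_world_grid(map_vol, map_slice)
    vox = inv_src @ world
    si = np.rint(vox[0]).astype(int)
    sj = np.rint(vox[1]).astype(int)
    in_field = (si >= 0) & (si < snx) & (sj >= 0) & (sj < sny)
    lab = np.zeros(si.shape, dtype=np.int16)
    lab[in_field] = labels.data[si[in_field], sj[in_field], source_slice]
    return (lab == label_value).reshape(nx, ny)


def transfer_labels(
    labels: LabelMap,
    map_vol: Volume,
    correspondence: SliceCorrespondence,
    mode: str = "slice",
) -> dict[str, ROIMask]:
    """Per-segment ROI masks on the map grid.

    Vessel labels are excluded (they are neither parenchyma ROI nor
    background) and out-of-field / background voxels carry no ROI.  Only
    segments with at least one transferred voxel appear in the result.
    """
    grid = transfer_label_grid(labels, map_vol, correspondence, mode=mode)
    slice_used = [s for _m, s, _d in sorted(correspondence, key=lambda e: e[0])]
    masks: dict[str, ROIMask] = {}
    for value, name in labels.scheme.items():
        if name not in SEGMENT_NAMES:
            continue
        m = grid == value
        if not m.any():
            continue
        masks[name] = ROIMask(
            segment=name,
            map_sequence_id=map_vol.sequence_id,
            mask=m,
            source_slice_used=list(slice_used),
        )
    return masks
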