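"""Quality-control gates applied to transferred ROIs before quantification.

Five configurable components guard the measurement against the failure
modes of purely geometric label transfer:

1. **ROI erosion** — strips the ROI boundary where partial-volume and
   registration ambiguity live (per-slice 2-D binary erosion).
2. **NCC source-slice subselection** — if the patient breathed between
   acquisitions the matched anatomical slice no longer shows the tissue the
   map slice samples; a neighboring source slice with higher zero-normalized
   cross-correlation inside the ROI is substituted.
3. **Outlier removal** — voxels outside ``total-liver median ± k·MAD``
   (raw median absolute deviation, default k = 3) are dropped; the band is
   computed once per map over the union of all segment ROIs.
4. **High-entropy detection** — a ROI whose intensity histogram entropy is
   too high (noise, artifacts) is omitted entirely.
5. **Minimum ROI size** — segments with too few analyzed voxels are omitted
   rather than reported from an unreliable sample.

The gates are applied in the order erosion -> subselection -> outlier
removal -> entropy -> minimum size, so the final voxel count reflects every
removal.  All operators are non-expanding: the quantified voxel set is
always a subset of the transferred ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from scipy import ndimage

from .label_transfer import ROIMask
from .volume_io import Volume

__all__ = [
    "QCConfig",
    "QCOutcome",
    "ENTROPY_VARIANTS",
    "EROSION_ITERATIONS",
    "erode_roi",
    "min_size_gate",
    "remove_outliers",
    "spatial_entropy",
    "entropy_gate",
    "subselect_source_slice",
]

#: The four entropy-gate variants: histogram bin count and threshold in
#: bits.  Thresholds sit a fixed margin below the bin count's maximal
#: entropy log2(bins): 1.5 bits for the strict variants, 0.5 for the
#: lenient ones.  These are calibration parameters, configurable per site.
ENTROPY_VARIANTS: dict[str, tuple[int, float]] = {
    "strict32": (32, 3.5),
    "lenient32": (32, 4.5),
    "strict64": (64, 4.5),
    "lenient64": (64, 5.5),
}

EROSION_ITERATIONS: dict[str, int] = {"none": 0, "small": 1, "large": 2}

#: 3x3 cross (4-connected) structuring element used for in-plane erosion.
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class QCConfig:
    """The five QC hyperparameters.

    ``entropy_variant`` is one of :data:`ENTROPY_VARIANTS` or ``None`` (gate
    off); ``outlier_rule`` is ``"off"`` or ``"mad3"`` with multiplier
    ``outlier_k``; ``subselection_neighborhood`` counts slices on each side
    of the matched source slice.
    """

    erosion_level: str = "none"
    min_roi_size: int = 50
    outlier_rule: str = "mad3"
    outlier_k: float = 3.0
    entropy_variant: str | None = "strict64"
    subselection_enabled: bool = False
    subselection_neighborhood: int = 2

    def __post_init__(self) -> None:
        if self.erosion_level not in EROSION_ITERATIONS:
            raise ValueError(f"erosion_level must be one of {sorted(EROSION_ITERATIONS)}")
        if self.min_roi_size < 1:
            raise ValueError("min_roi_size must be >= 1")
        if self.outlier_rule not in ("off", "mad3"):
            raise ValueError("outlier_rule must be 'off' or 'mad3'")
        if self.entropy_variant is not None and self.entropy_variant not in ENTROPY_VARIANTS:
            raise ValueError(f"entropy_variant must be None or one of {sorted(ENTROPY_VARIANTS)}")
        if self.subselection_enabled and self.subselection_neighborhood < 1:
            raise ValueError("subselection neighborhood must be >= 1 when enabled")

    @classmethod
    def optimized(cls) -> "QCConfig":
        """The best grid-search configuration shipped as a named preset:
        no erosion, minimum 50 analyzed voxels, total-liver median ± 3·MAD
        outlier removal, and high-entropy detection."""
        return cls(
            erosion_level="none",
            min_roi_size=50,
            outlier_rule="mad3",
            outlier_k=3.0,
            entropy_variant="strict64",
            subselection_enabled=False,
        )

    def key(self) -> str:
        """Compact ``<erosion>_<ss>_<nbhd>_<entropy>_<minsize>`` identifier."""
        ent = self.entropy_variant or "off"
        ss = "ss" if self.subselection_enabled else "noss"
        nb = self.subselection_neighborhood if self.subselection_enabled else 0
        return f"{self.erosion_level}_{ss}_{nb}_{self.outlier_rule}_{ent}_{self.min_roi_size}"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QCConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "erosion_level": self.erosion_level,
                    "min_roi_size": self.min_roi_size,
                    "outlier_rule": self.outlier_rule,
                    "outlier_k": self.outlier_k,
                    "entropy_variant": self.entropy_variant,
                    "subselection_enabled": self.subselection_enabled,
                    "subselection_neighborhood": self.subselection_neighborhood,
                },
                fh,
            )


@dataclass
class QCOutcome:
    """Verdict of the QC chain for one segment on one map."""

    passed: bool
    reason: str  # ok | below_min_size | high_entropy | emptied_by_outlier_removal | no_segment_in_source
    voxels_before: int
    voxels_after: int

    def __post_init__(self) -> None:
        if self.passed != (self.reason == "ok"):
            raise ValueError("passed must hold exactly when reason is 'ok'")
        if self.voxels_after > self.voxels_before:
            raise ValueError("QC must not grow the ROI")


# -- individual gates -------------------------------------------------------

def erode_roi(mask: ROIMask, level: str) -> ROIMask:
    """Per-slice 2-D binary erosion with a 3x3 cross element.

    ``none`` leaves the mask untouched, ``small`` applies one iteration,
    ``large`` two.  Erosion never grows the mask and may empty it; the
    min-size gate handles emptied ROIs downstream.
    """
    iters = EROSION_ITERATIONS[level]
    if iters == 0:
        return mask
    out = np.zeros_like(mask.mask)
    for k in range(mask.mask.shape[2]):
        sl = mask.mask[:, :, k]
        if sl.any():
            out[:, :, k] = ndimage.binary_erosion(sl, structure=_CROSS, iterations=iters)
    return replace(mask, mask=out)


def erode_slice(mask2d: np.ndarray, level: str) -> np.ndarray:
    """2-D counterpart of :func:`erode_roi` for a single slice."""
    iters = EROSION_ITERATIONS[level]
    if iters == 0:
        return mask2d
    if not mask2d.any():
        return mask2d
    return ndimage.binary_erosion(mask2d, structure=_CROSS, iterations=iters)


def min_size_gate(mask: ROIMask | int, threshold: int) -> QCOutcome:
    """Pass iff the ROI holds at least ``threshold`` voxels.

    A count equal to the threshold passes ("minimally N analyzed voxels").
    """
    n = mask if isinstance(mask, (int, np.integer)) else mask.voxel_count
    ok = n >= threshold
    return QCOutcome(
        passed=bool(ok),
        reason="ok" if ok else "below_min_size",
        voxels_before=int(n),
        voxels_after=int(n),
    )


def remove_outliers(
    roi_values: Iterable[float],
    liver_median: float,
    liver_mad: float,
    k: float = 3.0,
) -> np.ndarray:
    """Retain values within ``liver_median ± k·liver_mad``.

    The band comes from the *total liver* (union of all segment ROIs on the
    map), so a locally corrupted segment cannot widen its own band.  MAD is
    the raw median absolute deviation without the 1.4826 normal-consistency
    factor.  A zero MAD (quantized or constant maps) retains everything —
    the degenerate alternative would empty the ROI.
    """
    vals = np.asarray(list(roi_values) if not isinstance(roi_values, np.ndarray) else roi_values,
                      dtype=float)
    if vals.size == 0 or liver_mad == 0:
        return vals
    keep = np.abs(vals - liver_median) <= k * liver_mad
    return vals[keep]


def outlier_band(liver_values: np.ndarray, k: float = 3.0) -> tuple[float, float, float]:
    """(median, MAD, half-width k·MAD) of the pooled total-liver voxel values."""
    vals = np.asarray(liver_values, dtype=float)
    if vals.size == 0:
        return (math.nan, math.nan, math.nan)
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, mad, k * mad


def spatial_entropy(
    roi_values: Iterable[float],
    bins: int,
    value_range: tuple[float, float],
) -> float:
    """Shannon entropy (bits) of the ROI intensity histogram.

    The histogram spans the sequence's nominal intensity range so the
    measure is comparable across ROIs; empty bins contribute nothing.  A
    clean parenchymal ROI concentrates in a few bins (low entropy); noise
    or artifact spreads mass across many (high entropy).
    """
    vals = np.asarray(list(roi_values) if not isinstance(roi_values, np.ndarray) else roi_values,
                      dtype=float)
    if vals.size == 0:
        raise ValueError("spatial entropy is undefined for an empty ROI")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    lo, hi = value_range
    if not hi > lo:
        raise ValueError("value_range must satisfy hi > lo")
    counts, _ = np.histogram(vals, bins=bins, range=(lo, hi))
    total = counts.sum()
    if total == 0:  # every value outside the nominal range
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy_gate(
    roi_values: Iterable[float],
    variant: str | None,
    value_range: tuple[float, float],
) -> QCOutcome:
    """Fail with ``high_entropy`` iff the ROI entropy exceeds the variant threshold."""
    vals = np.asarray(list(roi_values) if not isinstance(roi_values, np.ndarray) else roi_values,
                      dtype=float)
    n = int(vals.size)
    if variant is None:
        return QCOutcome(True, "ok", n, n)
    bins, threshold = ENTROPY_VARIANTS[variant]
    h = spatial_entropy(vals, bins, value_range)
    ok = h <= threshold
    return QCOutcome(
        passed=bool(ok),
        reason="ok" if ok else "high_entropy",
        voxels_before=n,
        voxels_after=n if ok else 0,
    )


# -- NCC source-slice subselection -----------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation (Pearson r) of two value vectors."""
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return -np.inf
    return float((a @ b) / (na * nb))


def subselect_source_slice(
    map_vol: Volume,
    source_vol: Volume,
    mask2d: np.ndarray,
    map_slice: int,
    matched_index: int,
    neighborhood: int,
) -> int:
    """Pick the source slice in ``matched_index ± neighborhood`` that best
    matches the map slice inside the ROI.

    For every candidate slice the source intensities are sampled (bilinear)
    at the world positions of the ROI's map voxels, and the zero-normalized
    cross-correlation against the map intensities is computed.  The argmax
    wins; ties break toward the smaller offset, then the lower index.  A ROI
    with zero intensity variance leaves NCC undefined and the matched slice
    is kept.

    The correlation is evaluated on the ROI interior (the mask eroded by up
    to two iterations, kept only while enough voxels remain): boundary
    voxels mix tissues and track the ROI outline rather than the tissue the
    map slice samples, which systematically biases the alignment score.
    """
    for iters in (2, 1):
        interior = ndimage.binary_erosion(mask2d, structure=_CROSS, iterations=iters)
        if interior.sum() >= 20:
            mask2d = interior
            break
    pts = np.argwhere(mask2d)
    if pts.size == 0:
        return matched_index
    map_vals = map_vol.data[pts[:, 0], pts[:, 1], map_slice].astype(float)
    if map_vals.std() == 0:
        return matched_index
    if neighborhood < 1:
        return matched_index
    # world positions of the ROI's map voxel centres
    n = pts.shape[0]
    idx = np.stack([pts[:, 0], pts[:, 1], np.full(n, float(map_slice)), np.ones(n)])
    world = map_vol.affine @ idx
    vox = np.linalg.inv(source_vol.affine) @ world  # continuous source indices
    candidates = sorted(
        {
            int(np.clip(matched_index + off, 0, source_vol.n_slices - 1))
            for off in range(-neighborhood, neighborhood + 1)
        }
    )
    best = (None, matched_index)  # (score key, slice)
    for s in candidates:
        svals = ndimage.map_coordinates(
            np.asarray(source_vol.data[:, :, s], dtype=float),
            [vox[0], vox[1]],
            order=1,
            mode="nearest",
        )
        score = _ncc(map_vals, svals)
        if not np.isfinite(score):
            continue
        # lexicographic: higher NCC, then smaller |offset|, then lower index
        key = (score, -abs(s - matched_index), -s)
        if best[0] is None or key > best[0]:
            best = (key, s)
    return best[1]
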