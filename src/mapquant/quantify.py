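"""Per-exam pipeline: label transfer -> QC -> volumetric ROI statistics.

The measurement reported per segment and sequence is the mean voxel value
pooled over every retained voxel on all axial map slices containing the
ROI.  Pooling is equivalent to averaging per-slice means weighted by the
per-slice voxel counts, which is the convention manual readers use when a
segment spans several slices.  The total-liver value per sequence pools the
union of all segments that passed QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import qc as _qc
from .label_transfer import ROIMask, transfer_labels, transfer_segment_slice
from .qc import QCConfig, QCOutcome
from .volume_io import LabelMap, Volume, match_slices, SEGMENT_NAMES

__all__ = ["SegmentMeasurement", "ExamResult", "quantify_segment", "run_exam"]

log = logging.getLogger("mapquant")

#: fallback nominal intensity ranges for the entropy gate when a map volume
#: does not declare one (12-bit maps; T2 maps are stored at 0.1 ms scale).
DEFAULT_INTENSITY_RANGES = {
    "t1_pre": (0.0, 4095.0),
    "t1_post": (0.0, 4095.0),
    "t2": (0.0, 409.5),
}
FALLBACK_INTENSITY_RANGE = (0.0, 4095.0)


@dataclass
class SegmentMeasurement:
    """One segment x sequence result: a value or a reasoned omission."""

    exam_id: str
    sequence_id: str
    segment: str
    status: QCOutcome
    mean_value: float | None = None
    median_value: float | None = None
    voxel_count: int = 0
    per_slice_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status.passed != (self.mean_value is not None):
            raise ValueError("mean_value must be present exactly when QC passed")
        if self.per_slice_counts and self.voxel_count != sum(self.per_slice_counts):
            raise ValueError("voxel_count must equal the per-slice sum")


@dataclass
class ExamResult:
    """All segment measurements of one exam plus per-sequence total liver."""

    exam_id: str
    measurements: list[SegmentMeasurement]
    total_liver: dict[str, dict[str, float]]  # sequence_id -> {mean, median, voxels}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "exam_id": m.exam_id,
                    "sequence_id": m.sequence_id,
                    "segment": m.segment,
                    "mean_ms": m.mean_value,
                    "median_ms": m.median_value,
                    "voxels": m.voxel_count,
                    "status": "passed" if m.status.passed else "omitted",
                    "reason": m.status.reason,
                }
            )
        for seq, tot in self.total_liver.items():
            rows.append(
                {
                    "exam_id": self.exam_id,
                    "sequence_id": seq,
                    "segment": "total_liver",
                    "mean_ms": tot["mean"],
                    "median_ms": tot["median"],
                    "voxels": int(tot["voxels"]),
                    "status": "passed",
                    "reason": "ok",
                }
            )
        return pd.DataFrame(rows)


def quantify_segment(map_vol: Volume, mask: ROIMask, status: QCOutcome,
                     exam_id: str = "exam") -> SegmentMeasurement:
    """Volumetric ROI mean/median over all retained voxels of a passed mask."""
    if not status.passed:
        raise ValueError("quantify_segment called on a mask that failed QC")
    vals = np.asarray(map_vol.data[mask.mask], dtype=float)
    return SegmentMeasurement(
        exam_id=exam_id,
        sequence_id=map_vol.sequence_id,
        segment=mask.segment,
        status=status,
        mean_value=float(vals.mean()),
        median_value=float(np.median(vals)),
        voxel_count=int(vals.size),
        per_slice_counts=mask.per_slice_counts(),
    )


def _intensity_range(map_vol: Volume) -> tuple[float, float]:
    if map_vol.intensity_range is not None:
        return map_vol.intensity_range
    return DEFAULT_INTENSITY_RANGES.get(map_vol.sequence_id, FALLBACK_INTENSITY_RANGE)


def _apply_subselection(
    labels: LabelMap,
    map_vol: Volume,
    source_vol: Volume,
    mask: ROIMask,
    config: QCConfig,
) -> ROIMask:
    """Re-anchor each map slice of one segment ROI to the best NCC source slice."""
    label_value = labels.label_of(mask.segment)
    new_mask = mask.mask.copy()
    used = list(mask.source_slice_used)
    for k in range(map_vol.n_slices):
        if not mask.mask[:, :, k].any():
            continue
        matched = used[k]
        chosen = _qc.subselect_source_slice(
            map_vol, source_vol, mask.mask[:, :, k], k, matched,
            config.subselection_neighborhood,
        )
        if chosen != matched:
            sl = transfer_segment_slice(labels, map_vol, k, chosen, label_value)
            new_mask[:, :, k] = _qc.erode_slice(sl, config.erosion_level)
            used[k] = chosen
            log.debug("subselection %s slice %d: source %d -> %d",
                      mask.segment, k, matched, chosen)
    return replace(mask, mask=new_mask, source_slice_used=used)


def run_exam(
    source: Volume,
    labels: LabelMap,
    maps: list[Volume],
    config: QCConfig,
    exam_id: str = "exam",
    transfer_mode: str = "slice",
) -> ExamResult:
    """Run the full pipeline on one exam.

    Deterministic given inputs and configuration.  Every segment present in
    the label volume yields, per sequence, either a measurement or an
    omission with a reason; segments entirely absent from the transferred
    grid are omitted as ``no_segment_in_source``.
    """
    measurements: list[SegmentMeasurement] = []
    total_liver: dict[str, dict[str, float]] = {}
    segment_names = [v for _k, v in sorted(labels.scheme.items()) if v in SEGMENT_NAMES]

    for map_vol in maps:
        corr = match_slices(map_vol, source)
        masks = transfer_labels(labels, map_vol, corr, mode=transfer_mode)

        transferred_counts = {s: m.voxel_count for s, m in masks.items()}

        # erosion
        if config.erosion_level != "none":
            masks = {s: _qc.erode_roi(m, config.erosion_level) for s, m in masks.items()}

        # NCC source-slice subselection (per segment, per map slice)
        if config.subselection_enabled:
            masks = {
                s: _apply_subselection(labels, map_vol, source, m, config)
                for s, m in masks.items()
            }

        # total-liver outlier band over the union of all segment ROIs
        union = np.zeros(map_vol.data.shape, dtype=bool)
        for m in masks.values():
            union |= m.mask
        liver_median, liver_mad, _half = _qc.outlier_band(
            map_vol.data[union], config.outlier_k
        )

        vrange = _intensity_range(map_vol)
        passed_union = np.zeros(map_vol.data.shape, dtype=bool)

        for seg in segment_names:
            mask = masks.get(seg)
            before = transferred_counts.get(seg, 0)
            if mask is None or not mask.mask.any():
                # never transferred vs. annihilated by erosion
                reason = "no_segment_in_source" if before == 0 else "below_min_size"
                status = QCOutcome(False, reason, before, 0)
                measurements.append(SegmentMeasurement(
                    exam_id=exam_id, sequence_id=map_vol.sequence_id,
                    segment=seg, status=status))
                log.info("%s %s %s omitted: %s", exam_id, map_vol.sequence_id,
                         seg, status.reason)
                continue

            retained = mask.mask
            if config.outlier_rule == "mad3" and liver_mad > 0:
                in_band = np.abs(map_vol.data - liver_median) <= config.outlier_k * liver_mad
                retained = retained & in_band
            retained_mask = replace(mask, mask=retained)
            n_after = retained_mask.voxel_count

            if n_after == 0:
                status = QCOutcome(False, "emptied_by_outlier_removal", before, 0)
            else:
                ent = _qc.entropy_gate(
                    map_vol.data[retained], config.entropy_variant, vrange
                )
                if not ent.passed:
                    status = QCOutcome(False, "high_entropy", before, 0)
                elif n_after < config.min_roi_size:
                    status = QCOutcome(False, "below_min_size", before, n_after)
                else:
                    status = QCOutcome(True, "ok", before, n_after)

            if status.passed:
                measurements.append(
                    quantify_segment(map_vol, retained_mask, status, exam_id=exam_id)
                )
                passed_union |= retained
            else:
                measurements.append(SegmentMeasurement(
                    exam_id=exam_id, sequence_id=map_vol.sequence_id,
                    segment=seg, status=status))
                log.info("%s %s %s omitted: %s (%d -> %d voxels)", exam_id,
                         map_vol.sequence_id, seg, status.reason, before,
                         status.voxels_after)

        if passed_union.any():
            vals = np.asarray(map_vol.data[passed_union], dtype=float)
            total_liver[map_vol.sequence_id] = {
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "voxels": float(vals.size),
            }

    return ExamResult(exam_id=exam_id, measurements=measurements,
                      total_liver=total_liver)
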