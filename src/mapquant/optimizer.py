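"""Grid search over QC configurations against a reference reader.

Every configuration in the grid is run through the full pipeline on an
optimization dataset; per segment x sequence cell the automated values are
paired with the manual readings and scored with ICC(1,1).  Configurations
are ranked by a scalar objective balancing three criteria:

    f = mean_ICC - alpha * sd_ICC + beta * coverage

with coverage = performed measurements / manual measurements.  Higher mean
reliability, lower reliability spread and more measurements are all
rewarded; the default weights alpha = beta = 1 are configurable so a
site-specific trade-off can be restored.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import ENTROPY_VARIANTS, QCConfig
from .quantify import run_exam
from .volume_io import LabelMap, Volume

__all__ = ["ConfigScore", "objective_f", "default_grid", "iterate_grid", "grid_search"]

log = logging.getLogger("mapquant")


@dataclass
class ConfigScore:
    config: QCConfig
    mean_icc: float
    icc_sd: float
    n_measurements: int
    n_manual: int
    f_score: float

    @property
    def coverage(self) -> float:
        return self.n_measurements / self.n_manual if self.n_manual else 0.0


def objective_f(
    mean_icc: float,
    icc_sd: float,
    coverage: float,
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Scalar configuration score; strictly increasing in mean ICC and
    coverage, strictly decreasing in ICC spread."""
    if not 0.0 <= coverage <= 1.0 + 1e-12:
        raise ValueError("coverage must lie in [0, 1]")
    alpha, beta = weights
    return float(mean_icc - alpha * icc_sd + beta * coverage)


def default_grid() -> dict[str, list]:
    """The full hyperparameter lattice explored during optimization."""
    return {
        "erosion_level": ["none", "small", "large"],
        "min_roi_size": [50, 75, 100],
        "outlier_rule": ["off", "mad3"],
        "entropy_variant": [None, *sorted(ENTROPY_VARIANTS)],
        "subselection": ["off", 2, 3],
    }


def iterate_grid(grid: dict[str, list]) -> list[QCConfig]:
    """Materialize every combination of a (possibly partial) grid."""
    full = default_grid()
    full.update(grid or {})
    configs = []
    for ero, msize, orule, evar, ss in itertools.product(
        full["erosion_level"], full["min_roi_size"], full["outlier_rule"],
        full["entropy_variant"], full["subselection"],
    ):
        configs.append(QCConfig(
            erosion_level=ero,
            min_roi_size=msize,
            outlier_rule=orule,
            entropy_variant=evar,
            subselection_enabled=ss != "off",
            subselection_neighborhood=ss if ss != "off" else 2,
        ))
    return configs


@dataclass
class OptimizationExam:
    """One optimization-dataset exam: volumes plus its manual reading table."""

    exam_id: str
    source: Volume
    labels: LabelMap
    maps: list[Volume] = field(default_factory=list)


def _score_config(
    config: QCConfig,
    exams: list[OptimizationExam],
    manual: pd.DataFrame,
    weights: tuple[float, float],
    min_pairs: int,
) -> ConfigScore | None:
    from .reliability import icc_1_1  # local import to avoid cycle at module load

    autos = []
    for exam in exams:
        res = run_exam(exam.source, exam.labels, exam.maps, config, exam_id=exam.exam_id)
        df = res.to_dataframe()
        autos.append(df[df.segment != "total_liver"])
    auto = pd.concat(autos, ignore_index=True)
    passed = auto[auto.status == "passed"]
    merged = manual.merge(
        passed[["exam_id", "sequence_id", "segment", "mean_ms"]],
        on=["exam_id", "sequence_id", "segment"],
        how="left",
    )
    iccs = []
    for (_seq, _seg), cell in merged.groupby(["sequence_id", "segment"]):
        complete = cell.dropna(subset=["value_ms", "mean_ms"])
        if len(complete) < min_pairs:
            continue
        iccs.append(icc_1_1(complete[["value_ms", "mean_ms"]].to_numpy()).icc)
    if not iccs:
        warnings.warn(f"config {config.key()}: no cell with >= {min_pairs} pairs; skipped",
                      stacklevel=2)
        return None
    mean_icc = float(np.mean(iccs))
    icc_sd = float(np.std(iccs))
    n_meas = int(len(passed))
    n_manual = int(len(manual))
    coverage = min(n_meas / n_manual, 1.0) if n_manual else 0.0
    return ConfigScore(
        config=config,
        mean_icc=mean_icc,
        icc_sd=icc_sd,
        n_measurements=n_meas,
        n_manual=n_manual,
        f_score=objective_f(mean_icc, icc_sd, coverage, weights),
    )


def grid_search(
    exams: list[OptimizationExam],
    manual: pd.DataFrame,
    grid: dict[str, list] | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
    min_pairs: int = 3,
) -> list[ConfigScore]:
    """Evaluate every grid configuration and return scores ranked best-first.

    ``manual`` holds the reference readings with columns ``exam_id``,
    ``sequence_id``, ``segment``, ``value_ms``.  Ranking is by f score,
    ties broken by higher coverage and then the configuration key, so the
    ordering is deterministic and independent of exam order.
    """
    configs = iterate_grid(grid or {})
    if not configs:
        raise ValueError("empty configuration grid")
    scores: list[ConfigScore] = []
    for config in configs:
        score = _score_config(config, exams, manual, weights, min_pairs)
        if score is not None:
            scores.append(score)
            log.info("config %s: f=%.4f meanICC=%.4f sd=%.4f n=%d", config.key(),
                     score.f_score, score.mean_icc, score.icc_sd, score.n_measurements)
    scores.sort(key=lambda s: (-s.f_score, -s.coverage, s.config.key()))
    return scores


def scores_to_dataframe(scores: list[ConfigScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "config": s.config.key(),
                "f_score": s.f_score,
                "mean_icc": s.mean_icc,
                "icc_sd": s.icc_sd,
                "n_measurements": s.n_measurements,
                "n_manual": s.n_manual,
                "coverage_pct": 100.0 * s.coverage,
            }
            for s in scores
        ]
    )
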