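"""Agreement and reliability statistics between automated and manual readings.

Implements the comparison battery used to validate automated segmental
relaxometry against a reference reader:

* ICC(1,1) — one-way random-effects, single-measure intraclass correlation
  (absolute agreement between two raters), with F-based 95% CI and p-value.
* Deming regression — errors-in-variables linear fit with error-variance
  ratio delta (default 1, i.e. orthogonal regression).
* Spearman's rho with mid-rank tie handling.
* Paired two-sided Wilcoxon signed-rank on the differences, with percentile
  bootstrap confidence intervals on the medians.
* A four-way agreement taxonomy of who measured what: positive agreement
  (both), negative agreement (neither), human-only (subdivided by the
  automated omission reason) and algorithm-only.

Interpretation bands for ICC follow the usual convention: below 0.5 poor,
0.5-0.75 moderate, 0.75-0.9 good, above 0.9 excellent reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCResult",
    "DemingFit",
    "MedianComparison",
    "icc_1_1",
    "deming_fit",
    "spearman_rho",
    "compare_medians",
    "categorize_agreement",
    "AGREEMENT_CATEGORIES",
]

#: omission reasons grouped under "QC omission" in the agreement taxonomy
QC_OMISSION_REASONS = ("below_min_size", "high_entropy", "emptied_by_outlier_removal")
AGREEMENT_CATEGORIES = ("positive_agreement", "negative_agreement", "human_only", "algorithm_only")


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    p_value: float
    n_pairs: int


@dataclass
class DemingFit:
    slope: float
    intercept: float
    delta: float = 1.0


@dataclass
class MedianComparison:
    median_auto: float
    median_manual: float
    median_of_differences: float
    wilcoxon_p: float
    ci95_differences: tuple[float, float]
    ci95_auto: tuple[float, float]
    ci95_manual: tuple[float, float]
    n_pairs: int
    degenerate: bool = False


def _pairs_array(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (manual, auto) values")
    if np.any(~np.isfinite(arr)):
        raise ValueError("pairs must be complete (no NaN/inf); drop incomplete rows first")
    return arr


def icc_1_1(pairs, alpha: float = 0.05) -> ICCResult:
    """One-way random, single-measure intraclass correlation, ICC(1,1).

    Each pair (manual, auto) is one target rated by k = 2 raters under the
    one-way random model.  With the between- and within-target mean squares
    MSB and MSW from a one-way ANOVA,

        ICC = (MSB - MSW) / (MSB + (k-1) MSW)

    The confidence interval and p-value use the exact F formulation
    (F = MSB/MSW with n-1 and n(k-1) degrees of freedom).
    """
    arr = _pairs_array(pairs)
    n, k = arr.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 complete pairs")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssw = ((arr - row_means[:, None]) ** 2).sum()
    df_b = n - 1
    df_w = n * (k - 1)
    msb = ssb / df_b
    msw = ssw / df_w
    if msb <= 0 or (msb == 0 and msw == 0):
        warnings.warn("zero between-subject variance; ICC reported as 0", stacklevel=2)
        return ICCResult(icc=0.0, ci95=(0.0, 0.0), p_value=1.0, n_pairs=n)
    if msw == 0:
        # perfect agreement
        return ICCResult(icc=1.0, ci95=(1.0, 1.0), p_value=0.0, n_pairs=n)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    f_u = stats.f.ppf(1 - alpha / 2, df_b, df_w)
    f_l = stats.f.ppf(1 - alpha / 2, df_w, df_b)
    fl = f_obs / f_u
    fu = f_obs * f_l
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    p = float(stats.f.sf(f_obs, df_b, df_w))
    return ICCResult(icc=float(icc), ci95=(float(lo), float(hi)), p_value=p, n_pairs=n)


def deming_fit(x, y, delta: float = 1.0) -> DemingFit:
    """Closed-form Deming (errors-in-variables) regression of y on x.

    ``delta`` is the ratio of the y-error variance to the x-error variance;
    delta = 1 gives orthogonal regression, symmetric under axis swap
    (slope -> 1/slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("Deming regression requires n >= 3 equal-length arrays")
    if delta <= 0:
        raise ValueError("delta must be positive")
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum() / (x.size - 1)
    syy = ((y - ym) ** 2).sum() / (y.size - 1)
    sxy = ((x - xm) * (y - ym)).sum() / (x.size - 1)
    if sxx == 0 and syy == 0:
        raise ValueError("Deming regression undefined: zero variance on both axes")
    if sxy == 0:
        # no covariance: vertical/horizontal degenerate fit
        slope = 0.0 if syy < delta * sxx else np.inf
    else:
        term = syy - delta * sxx
        slope = (term + np.sqrt(term**2 + 4 * delta * sxy**2)) / (2 * sxy)
    intercept = ym - slope * xm
    return DemingFit(slope=float(slope), intercept=float(intercept), delta=delta)


def spearman_rho(pairs) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; (rho, p)."""
    arr = _pairs_array(pairs)
    if arr.shape[0] < 3:
        raise ValueError("Spearman correlation requires n >= 3")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        warnings.warn("constant column: Spearman rho undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
    return float(rho), float(p)


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the median.

    Resampling uses ``rng.integers(0, n, size=(n_boot, n))`` row-wise; the
    interval is the (alpha/2, 1-alpha/2) percentile of the resampled
    medians.  Fully determined by the seed.
    """
    values = np.asarray(values, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    lo, hi = np.percentile(meds, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return (float(lo), float(hi))


def compare_medians(
    pairs,
    n_boot: int = 10_000,
    seed: int = 0,
) -> MedianComparison:
    """Medians of both arms, median of differences, Wilcoxon p, bootstrap CIs.

    Differences are ``auto - manual``.  The CI of the median of differences
    resamples differences; the per-arm CIs resample pairs (keeping the two
    arms coupled).  All differences equal to zero is a degenerate case for
    the signed-rank test and is reported with p = 1.
    """
    arr = _pairs_array(pairs)
    n = arr.shape[0]
    if n < 5:
        raise ValueError("compare_medians requires n >= 5 pairs")
    manual, auto = arr[:, 0], arr[:, 1]
    diffs = auto - manual
    degenerate = bool(np.all(diffs == 0))
    if degenerate:
        p = 1.0
    else:
        p = float(stats.wilcoxon(auto, manual, alternative="two-sided").pvalue)
    rng = np.random.default_rng(seed)
    ci_diff = bootstrap_median_ci(diffs, n_boot=n_boot, seed=rng)
    # per-arm CIs from a common pair resampling
    idx = rng.integers(0, n, size=(n_boot, n))
    med_auto = np.median(auto[idx], axis=1)
    med_manual = np.median(manual[idx], axis=1)
    ci_auto = tuple(float(v) for v in np.percentile(med_auto, [2.5, 97.5]))
    ci_manual = tuple(float(v) for v in np.percentile(med_manual, [2.5, 97.5]))
    return MedianComparison(
        median_auto=float(np.median(auto)),
        median_manual=float(np.median(manual)),
        median_of_differences=float(np.median(diffs)),
        wilcoxon_p=p,
        ci95_differences=ci_diff,
        ci95_auto=ci_auto,
        ci95_manual=ci_manual,
        n_pairs=n,
        degenerate=degenerate,
    )


def categorize_agreement(table: pd.DataFrame) -> dict:
    """Count who-measured-what categories over an agreement table.

    ``table`` has one row per (exam, sequence, segment) with columns
    ``manual_value``, ``auto_value`` (NaN when absent) and optionally
    ``auto_omission_reason``.  Returns top-level counts plus the breakdown
    of human-only rows by automated omission reason:

    * ``no_segment_delineated`` — the source segmentation held no segment,
    * ``breathing_misalignment`` — flagged motion between acquisitions,
    * ``qc_omission`` — min-size / entropy / outlier-emptied gates.

    The four top-level counts always sum to ``len(table)``.
    """
    counts = {c: 0 for c in AGREEMENT_CATEGORIES}
    reasons = {"no_segment_delineated": 0, "breathing_misalignment": 0, "qc_omission": 0,
               "other": 0}
    for _, row in table.iterrows():
        has_manual = pd.notna(row.get("manual_value"))
        has_auto = pd.notna(row.get("auto_value"))
        if has_manual and has_auto:
            counts["positive_agreement"] += 1
        elif not has_manual and not has_auto:
            counts["negative_agreement"] += 1
        elif has_manual:
            counts["human_only"] += 1
            reason = row.get("auto_omission_reason")
            if reason == "no_segment_in_source":
                reasons["no_segment_delineated"] += 1
            elif reason == "breathing_misalignment":
                reasons["breathing_misalignment"] += 1
            elif reason in QC_OMISSION_REASONS:
                reasons["qc_omission"] += 1
            else:
                reasons["other"] += 1
        else:
            counts["algorithm_only"] += 1
    counts["human_only_reasons"] = reasons
    counts["total"] = int(len(table))
    return counts
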