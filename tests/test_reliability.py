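"""Agreement statistics vs independent from-scratch oracles."""

import numpy as np
import pandas as pd
import pytest

from mapquant.reliability import (
    bootstrap_median_ci,
    categorize_agreement,
    compare_medians,
    deming_fit,
    icc_1_1,
    spearman_rho,
)


def _icc_oracle(arr):
    """Explicit one-way ANOVA sums, independent of the implementation."""
    n, k = arr.shape
    grand = arr.sum() / arr.size
    ssb = sum(k * (row.mean() - grand) ** 2 for row in arr)
    ssw = sum(((row - row.mean()) ** 2).sum() for row in arr)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestICC:
    def test_identical_columns_give_one(self, rng):
        x = rng.normal(800, 40, 20)
        r = icc_1_1(np.column_stack([x, x]))
        assert r.icc == 1.0 and r.p_value == 0.0

    def test_matches_anova_oracle(self, rng):
        arr = np.column_stack([rng.normal(800, 40, 30), rng.normal(800, 40, 30)])
        assert icc_1_1(arr).icc == pytest.approx(_icc_oracle(arr), abs=1e-10)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(99)
        arr = rng.normal(0, 1, size=(10_000, 2))
        assert abs(icc_1_1(arr).icc) < 0.03

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(500, 30, 25)
        y = x + rng.normal(0, 10, 25)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(25), 2),
            "raters": np.tile(["manual", "auto"], 25),
            "score": np.column_stack([x, y]).ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="score")
        row = ref.iloc[0]
        assert row.Type.startswith("ICC(1") or row.Type == "ICC1"
        r = icc_1_1(np.column_stack([x, y]))
        assert r.icc == pytest.approx(row.ICC, abs=1e-8)
        assert r.ci95 == pytest.approx(tuple(row.CI95), abs=6e-3)  # pingouin rounds
        assert r.p_value == pytest.approx(row.pval, rel=1e-6)

    def test_ci_brackets_estimate_and_unit_invariance(self, rng):
        x = rng.normal(37, 4, 40)
        y = x + rng.normal(0, 1, 40)
        r = icc_1_1(np.column_stack([x, y]))
        assert r.ci95[0] <= r.icc <= r.ci95[1]
        r_s = icc_1_1(np.column_stack([x / 1000, y / 1000]))  # ms -> s
        assert r_s.icc == pytest.approx(r.icc, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_1_1([(1.0, 1.1), (2.0, 2.1)])


class TestDeming:
    def test_identity_line_exact(self, rng):
        x = rng.normal(500, 50, 30)
        fit = deming_fit(x, x)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_swap_symmetry_at_delta_one(self, rng):
        x = rng.normal(800, 40, 50)
        y = 0.9 * x + rng.normal(0, 15, 50)
        assert deming_fit(x, y).slope * deming_fit(y, x).slope == pytest.approx(1.0, abs=1e-10)

    def test_recovers_unit_slope_under_equal_noise(self):
        """Simulation oracle: y = x + equal-variance noise on both axes."""
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = rng.normal(800, 60, 500)
            x = t + rng.normal(0, 10, 500)
            y = t + rng.normal(0, 10, 500)
            slopes.append(deming_fit(x, y).slope)
        assert all(0.97 <= s <= 1.03 for s in slopes)

    def test_unit_change_scales_intercept_not_slope(self, rng):
        x = rng.normal(500, 50, 40)
        y = 1.1 * x + rng.normal(0, 5, 40) + 30
        fit_ms = deming_fit(x, y)
        fit_s = deming_fit(x / 1000, y / 1000)
        assert fit_s.slope == pytest.approx(fit_ms.slope, abs=1e-9)
        assert fit_s.intercept == pytest.approx(fit_ms.intercept / 1000, abs=1e-9)

    def test_double_constant_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            deming_fit([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


class TestSpearman:
    def test_monotone_transform_is_one(self, rng):
        x = rng.normal(0, 1, 30)
        rho, _ = spearman_rho(np.column_stack([x, np.exp(x)]))
        assert rho == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman_rho(np.column_stack([x, -x]))
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        from scipy.stats import rankdata

        x = rng.normal(0, 1, 50)
        y = x + rng.normal(0, 1, 50)
        rho, _ = spearman_rho(np.column_stack([x, y]))
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_rho([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])
        assert np.isnan(rho)


class TestCompareMedians:
    def test_identical_arms_degenerate(self, rng):
        x = rng.normal(37, 4, 20)
        mc = compare_medians(np.column_stack([x, x]))
        assert mc.median_of_differences == 0.0
        assert mc.wilcoxon_p == 1.0 and mc.degenerate

    def test_constant_shift_detected(self, rng):
        x = rng.normal(835, 30, 50)
        mc = compare_medians(np.column_stack([x, x + 5.0]))
        assert mc.median_of_differences == pytest.approx(5.0)
        assert mc.wilcoxon_p < 0.001

    def test_bootstrap_matches_same_seed_oracle(self, rng):
        vals = rng.normal(0, 1, 40)
        got = bootstrap_median_ci(vals, n_boot=2000, seed=7)
        # independently coded percentile bootstrap with the same resampler
        oracle_rng = np.random.default_rng(7)
        idx = oracle_rng.integers(0, 40, size=(2000, 40))
        meds = np.median(vals[idx], axis=1)
        lo, hi = np.percentile(meds, [2.5, 97.5])
        assert got == (pytest.approx(lo), pytest.approx(hi))

    def test_ci_of_differences_brackets_shift(self, rng):
        x = rng.normal(518, 30, 80)
        mc = compare_medians(np.column_stack([x, x + 2.0]), seed=3)
        lo, hi = mc.ci95_differences
        assert lo <= 2.0 <= hi


class TestAgreementTaxonomy:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["exam_id", "sequence_id", "segment",
                                           "manual_value", "auto_value",
                                           "auto_omission_reason"])

    def test_all_measured_is_pure_positive_agreement(self):
        t = self._table([("e", "t2", s, 30.0, 31.0, None) for s in "ABCDE"])
        c = categorize_agreement(t)
        assert c["positive_agreement"] == 5 and c["total"] == 5
        assert c["negative_agreement"] == c["human_only"] == c["algorithm_only"] == 0

    def test_constructed_ten_row_hand_count(self):
        rows = [("e", "t2", str(i), 30.0, 31.0, None) for i in range(7)]
        rows += [("e", "t2", "h1", 30.0, np.nan, "below_min_size"),
                 ("e", "t2", "h2", 30.0, np.nan, "high_entropy"),
                 ("e", "t2", "n1", np.nan, np.nan, None)]
        c = categorize_agreement(self._table(rows))
        assert (c["positive_agreement"], c["negative_agreement"],
                c["human_only"], c["algorithm_only"]) == (7, 1, 2, 0)
        assert c["human_only_reasons"]["qc_omission"] == 2

    def test_omission_reason_subdivision(self):
        rows = [("e", "t2", "a", 30.0, np.nan, "no_segment_in_source"),
                ("e", "t2", "b", 30.0, np.nan, "breathing_misalignment"),
                ("e", "t2", "c", 30.0, np.nan, "emptied_by_outlier_removal"),
                ("e", "t2", "d", np.nan, 31.0, None)]
        c = categorize_agreement(self._table(rows))
        r = c["human_only_reasons"]
        assert (r["no_segment_delineated"], r["breathing_misalignment"],
                r["qc_omission"]) == (1, 1, 1)
        assert c["algorithm_only"] == 1

    def test_empty_table_all_zeros(self):
        c = categorize_agreement(self._table([]))
        assert all(c[k] == 0 for k in ("positive_agreement", "negative_agreement",
                                       "human_only", "algorithm_only", "total"))

    def test_partition_property_random_tables(self):
        """Counts always partition the table (100 random tables)."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 40))
            manual = np.where(rng.random(n) < 0.8, rng.normal(500, 30, n), np.nan)
            auto = np.where(rng.random(n) < 0.8, rng.normal(500, 30, n), np.nan)
            reasons = rng.choice(["below_min_size", "high_entropy",
                                  "no_segment_in_source", "breathing_misalignment"], n)
            t = self._table([("e", "t1_pre", str(i), manual[i], auto[i],
                              reasons[i] if np.isnan(auto[i]) else None)
                             for i in range(n)])
            c = categorize_agreement(t)
            top = (c["positive_agreement"] + c["negative_agreement"]
                   + c["human_only"] + c["algorithm_only"])
            assert top == n
            assert sum(c["human_only_reasons"].values()) == c["human_only"]
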