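"""Precision/accuracy statistics and the model/results interface."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ctvolumetry import (
    VolumetryAccuracyModel,
    accuracy_slope,
    anova_oneway_bonferroni,
    ci95,
    cov,
    error_summary,
    lookup_min_diameter,
)


class TestCov:
    def test_constant_values(self):
        assert cov([5, 5, 5, 5, 5]) == 0.0

    def test_hand_computed(self):
        assert cov([1, 2, 3]) == pytest.approx(50.0)  # sd 1, mean 2

    def test_scale_invariance(self, rng):
        x = rng.uniform(1, 10, size=8)
        assert cov(7.3 * x) == pytest.approx(cov(x))

    @pytest.mark.parametrize("bad", [[1.0], [1.0, -1.0]])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            cov(bad)


class TestCi95:
    def test_constant_values_zero_width(self):
        lo, hi = ci95([4.2, 4.2, 4.2])
        assert lo == hi == pytest.approx(4.2)

    def test_closed_form_n5(self):
        x = [1, 2, 3, 4, 5]
        sd = np.std(x, ddof=1)
        t975 = 2.7764451051977987  # t(0.975, 4)
        half = t975 * sd / np.sqrt(5)
        lo, hi = ci95(x)
        assert lo == pytest.approx(3 - half)
        assert hi == pytest.approx(3 + half)

    def test_contains_mean(self, rng):
        x = rng.normal(10, 2, size=6)
        lo, hi = ci95(x)
        assert lo <= x.mean() <= hi

    def test_single_value_raises(self):
        with pytest.raises(ValueError):
            ci95([1.0])


class TestAccuracySlope:
    def test_unity_line(self):
        pairs = [(v, v) for v in (10.0, 100.0, 1000.0)]
        res = accuracy_slope(pairs)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_proportionality(self):
        pairs = [(v, 0.9 * v) for v in (16.8, 134.0, 8580.0)]
        assert accuracy_slope(pairs).slope == pytest.approx(0.9)

    def test_matches_grid_search_minimizer(self, rng):
        x = rng.uniform(10, 1000, size=20)
        y = 0.85 * x + rng.normal(0, 20, size=20)
        res = accuracy_slope(np.column_stack([x, y]))
        grid = np.linspace(0.5, 1.2, 14001)
        sse = ((y[None, :] - grid[:, None] * x[None, :]) ** 2).sum(axis=1)
        assert res.slope == pytest.approx(grid[np.argmin(sse)], abs=1e-4)

    def test_r_squared_in_unit_interval(self, rng):
        x = rng.uniform(1, 100, size=15)
        y = 0.8 * x + rng.normal(0, 30, size=15)
        r2 = accuracy_slope(np.column_stack([x, y])).r_squared
        assert 0.0 <= r2 <= 1.0

    def test_all_zero_truth_raises(self):
        with pytest.raises(ValueError):
            accuracy_slope([(0.0, 1.0), (0.0, 2.0)])


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = anova_oneway_bonferroni([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self, rng):
        a = rng.normal(0, 1, size=9)
        b = rng.normal(0.7, 1, size=12)
        res = anova_oneway_bonferroni([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.f_statistic == pytest.approx(t ** 2)
        assert res.p_value == pytest.approx(p)

    def test_bonferroni_multiplies_and_caps(self, rng):
        groups = [rng.normal(m, 1, size=6) for m in (0.0, 0.1, 5.0)]
        res = anova_oneway_bonferroni(groups, n_comparisons=3)
        raw01 = sps.ttest_ind(groups[0], groups[1], equal_var=True).pvalue
        assert res.pairwise_adjusted[(0, 1)] == pytest.approx(
            min(1.0, 3 * raw01))
        assert all(p <= 1.0 for p in res.pairwise_adjusted.values())

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            anova_oneway_bonferroni([[1.0], [2.0, 3.0]])


class TestLookupMinDiameter:
    def test_boundary_point(self):
        entry = lookup_min_diameter([(5.0, 30.0), (10.0, 10.0)], 10.0)
        assert entry.sentinel is None
        assert entry.min_diameter == pytest.approx(10.0)

    def test_linear_interpolation(self):
        entry = lookup_min_diameter([(5.0, 15.0), (10.0, 5.0)], 10.0)
        assert entry.min_diameter == pytest.approx(7.5)

    def test_all_above_tolerance_sentinel(self):
        entry = lookup_min_diameter([(5.0, 40.0), (25.4, 30.0)], 20.0)
        assert entry.sentinel == "> max tested"
        assert str(entry) == ">25.4"

    def test_all_below_tolerance_sentinel(self):
        entry = lookup_min_diameter([(3.2, 5.0), (25.4, 1.0)], 20.0)
        assert entry.sentinel == "< min tested"
        assert str(entry) == "<3.2"

    def test_non_monotone_curve_uses_last_crossing(self):
        # error dips below tolerance then rises again: the early dip
        # does not count
        curve = [(4.0, 30.0), (6.0, 8.0), (8.0, 12.0), (10.0, 5.0)]
        entry = lookup_min_diameter(curve, 10.0)
        assert 8.0 < entry.min_diameter < 10.0

    def test_monotone_in_tolerance(self):
        curve = [(4.0, 35.0), (8.0, 18.0), (16.0, 7.0), (25.4, 3.0)]
        d10 = lookup_min_diameter(curve, 10.0).min_diameter
        d20 = lookup_min_diameter(curve, 20.0).min_diameter
        assert d10 >= d20

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            lookup_min_diameter([(10.0, 5.0), (5.0, 15.0)], 10.0)


def _toy_table(rng):
    """Small synthetic measurement table over a 2x2x2 condition grid."""
    rows = []
    for fov in (20.0, 40.0):
        for kernel in ("standard", "lung"):
            for t in (0.625, 5.0):
                bias = {"standard": 0.88, "lung": 0.95}[kernel] - \
                    (0.08 if t == 5.0 else 0.0)
                for d, vt in ((6.35, 134.07), (12.7, 1072.5), (25.4, 8580.2)):
                    for rep in range(5):
                        vct = bias * vt * (1 + rng.normal(0, 0.02))
                        rows.append({
                            "sphere_id": f"r{rep}-d{d}", "diameter_mm": d,
                            "v_true_mm3": vt, "v_ct_mm3": vct,
                            "percent_error": (vct - vt) / vt * 100,
                            "detected": True, "n_fragments": 0,
                            "fov_cm": fov, "kernel": kernel,
                            "slice_thickness_mm": t,
                        })
    # one non-detection
    rows.append({"sphere_id": "r0-d3.2", "diameter_mm": 3.175,
                 "v_true_mm3": 16.76, "v_ct_mm3": np.nan,
                 "percent_error": np.nan, "detected": False,
                 "n_fragments": 0, "fov_cm": 20.0, "kernel": "standard",
                 "slice_thickness_mm": 0.625})
    return pd.DataFrame(rows)


class TestErrorSummary:
    def test_single_measurement_cell(self):
        df = pd.DataFrame([{"diameter_mm": 9.5, "percent_error": -12.0,
                            "detected": True, "fov_cm": 20.0,
                            "kernel": "lung", "slice_thickness_mm": 0.625}])
        out = error_summary(df)
        assert out.loc[0, "mean"] == out.loc[0, "median"] == -12.0
        assert out.loc[0, "n"] == 1

    def test_matches_flat_recomputation(self, rng):
        df = _toy_table(rng)
        out = error_summary(df)
        cell = out[(out.fov_cm == 20.0) & (out.kernel == "lung")
                   & (out.slice_thickness_mm == 5.0)
                   & (out.diameter_mm == 12.7)].iloc[0]
        ref = df[(df.fov_cm == 20.0) & (df.kernel == "lung")
                 & (df.slice_thickness_mm == 5.0) & (df.diameter_mm == 12.7)
                 & df.detected]["percent_error"]
        assert cell["mean"] == pytest.approx(ref.mean())
        assert cell["median"] == pytest.approx(ref.median())
        assert cell["se"] == pytest.approx(ref.std(ddof=1) / np.sqrt(len(ref)))

    def test_nondetections_do_not_shift_mean(self, rng):
        df = _toy_table(rng)
        base = error_summary(df)
        extra = df.iloc[[-1]].copy()  # one more non-detection
        out = error_summary(pd.concat([df, extra], ignore_index=True))
        pd.testing.assert_frame_equal(base, out)


class TestModelResults:
    def test_fit_tables_and_summary(self, rng):
        res = VolumetryAccuracyModel(_toy_table(rng)).fit()
        assert len(res.slopes) == 8
        assert (res.slopes.slope < 1).all()
        # thick slices less accurate than thin, per construction
        piv = res.slopes.pivot_table(index=["fov_cm", "kernel"],
                                     columns="slice_thickness_mm",
                                     values="slope")
        assert (piv[0.625] > piv[5.0]).all()
        assert {"diameter_mm", "kernel"} <= set(res.anovas)
        text = res.summary()
        assert "slope" in text and "ANOVA" in text

    def test_precision_table_cov_consistency(self, rng):
        res = VolumetryAccuracyModel(_toy_table(rng)).fit()
        row = res.precision.iloc[0]
        assert row["cov_pct"] == pytest.approx(
            row["sd_mm3"] / row["mean_v_ct_mm3"] * 100)
        assert row["ci95_low_mm3"] <= row["mean_v_ct_mm3"] \
            <= row["ci95_high_mm3"]

    def test_exclusions_drop_size_class(self, rng):
        df = _toy_table(rng)
        model = VolumetryAccuracyModel(df, exclude_diameters=(6.35,))
        assert 6.35 not in model.data["diameter_mm"].to_numpy()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            VolumetryAccuracyModel(pd.DataFrame({"percent_error": [1.0]}))

    def test_plots_return_axes(self, rng):
        import matplotlib
        matplotlib.use("Agg")
        res = VolumetryAccuracyModel(_toy_table(rng)).fit()
        ax1 = res.plot_percent_error(fov_cm=20.0, kernel="lung")
        assert ax1.get_xlabel() == "sphere diameter (mm)"
        ax2 = res.plot_slopes()
        assert len(ax2.lines) > 1
        matplotlib.pyplot.close("all")
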