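"""Stance metrics, aggregation, alteration selection, and statistics."""

import numpy as np
import pandas as pd
import pytest

from gaitload import outcomes as oc
from gaitload.published import GROUP_MEANS, mean_difference


class TestBMI:
    @pytest.mark.parametrize("mass,height,expected", [
        (74.0, 156.0, 30.41),
        (71.2, 167.5, 25.38),
        (100.0, 200.0, 25.00),
    ])
    def test_reported_two_decimals(self, mass, height, expected):
        assert oc.compute_bmi(mass, height) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            oc.compute_bmi(0, 170)


class TestStanceDetection:
    def test_recovers_known_window(self):
        rate = 2000.0
        t = np.arange(int(2.0 * rate)) / rate
        t0, t1 = 0.4, 1.1
        fz = np.where((t >= t0) & (t <= t1), 800.0, 0.0)   # sharp contact
        hs, to = oc.detect_stance(fz, rate)
        assert hs == pytest.approx(t0, abs=1.0 / rate)
        assert to == pytest.approx(t1, abs=1.0 / rate)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            oc.detect_stance(np.zeros(100), 2000.0)

    def test_threshold_above_peak_rejected(self):
        fz = 10 * np.sin(np.linspace(0, np.pi, 200))
        with pytest.raises(ValueError):
            oc.detect_stance(fz, 2000.0, threshold=20.0)


class TestResampleAndMetrics:
    def test_constant_force_closed_form(self):
        t = np.linspace(0, 1, 500)
        curve = oc.resample_stance(t, np.full(500, 700.0), (0.2, 0.9))
        m = oc.compute_metrics(curve, body_weight=700.0, kind="force")
        assert m.peak == pytest.approx(100.0)
        assert m.impulse == pytest.approx(100.0 * 0.7, rel=1e-9)

    def test_half_sine_impulse(self):
        """Impulse of A sin(pi t / T) over T is (2/pi) A T; the 101-point
        trapezoid matches within 0.1%."""
        T, A = 0.8, 900.0
        t = np.linspace(0, T, 4001)
        curve = oc.resample_stance(t, A * np.sin(np.pi * t / T), (0.0, T))
        m = oc.compute_metrics(curve)
        assert m.impulse == pytest.approx(2 / np.pi * A * T, rel=1e-3)
        assert m.peak == pytest.approx(A, rel=1e-3)

    def test_resampling_101_idempotent(self):
        t = np.linspace(0, 1, 101)
        vals = np.sin(t * 4)
        c1 = oc.resample_stance(t, vals, (0.0, 1.0))
        c2 = oc.resample_stance(np.linspace(0, 1, 101), c1.values, (0.0, 1.0))
        np.testing.assert_allclose(c2.values, c1.values, atol=1e-12)

    def test_events_outside_series_rejected(self):
        with pytest.raises(ValueError):
            oc.resample_stance(np.linspace(0, 1, 100), np.zeros(100), (0.5, 1.5))

    def test_peak_at_least_mean(self, rng):
        t = np.linspace(0, 1, 300)
        vals = np.abs(rng.normal(0, 100, 300))
        c = oc.resample_stance(t, vals, (0.1, 0.9))
        m = oc.compute_metrics(c)
        assert m.peak >= m.impulse / c.stance_duration
        assert m.impulse >= 0


class TestAggregation:
    def test_basic(self):
        mean, sd = oc.aggregate([1.0, 2.0, 3.0])
        assert mean == 2.0
        assert sd == pytest.approx(1.0)

    def test_identical_trials_zero_sd(self):
        _, sd = oc.aggregate([4.2, 4.2, 4.2])
        assert sd == 0.0

    def test_matches_pandas_oracle(self, rng):
        x = rng.normal(10, 3, 17)
        mean, sd = oc.aggregate(x)
        s = pd.Series(x)
        assert mean == pytest.approx(s.mean(), rel=1e-12)
        assert sd == pytest.approx(s.std(ddof=1), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            oc.aggregate([1.0])


class TestSelection:
    def test_published_linear_peak_pattern_selects_wide(self):
        means = GROUP_MEANS["linear"].loc["peak_mcf"].to_dict()
        assert oc.select_best_alteration(means).choice == "wide"

    def test_none_when_no_alteration_reduces(self):
        means = {c: 100.0 for c in oc.CONDITION_ORDER}
        means["shod"] = 90.0
        assert oc.select_best_alteration(means).choice == "none"

    def test_tie_breaks_canonically_and_flags(self):
        means = dict.fromkeys(oc.CONDITION_ORDER, 100.0)
        means["insole_5"] = 95.0
        means["toe_out"] = 95.0
        sel = oc.select_best_alteration(means)
        assert sel.choice == "insole_5"
        assert sel.tie

    def test_missing_condition_rejected(self):
        with pytest.raises(KeyError):
            oc.select_best_alteration({"shod": 1.0, "wide": 0.9})


class TestPairedDifferences:
    def test_balanced_identity(self, rng):
        """Mean of paired differences equals difference of condition means."""
        data = pd.DataFrame(rng.normal(200, 30, (5, 7)),
                            columns=list(oc.CONDITION_ORDER))
        tbl = oc.paired_difference_table(data)
        for cond in oc.CONDITION_ORDER[1:]:
            assert tbl.loc[cond, "mean_difference"] == pytest.approx(
                data["shod"].mean() - data[cond].mean(), rel=1e-12)

    def test_identical_conditions_zero(self):
        data = pd.DataFrame({"shod": [1.0, 2, 3, 4, 5],
                             "wide": [1.0, 2, 3, 4, 5]})
        tbl = oc.paired_difference_table(data)
        assert tbl.loc["wide", "mean_difference"] == 0.0
        assert tbl.loc["wide", "se"] == 0.0

    def test_individual_selection_row(self):
        data = pd.DataFrame({"shod": [10.0, 10, 10],
                             "toe_in": [9.0, 11, 10],
                             "wide": [8.0, 12, 9]})
        sel = {0: "wide", 1: "toe_in", 2: "none"}
        tbl = oc.paired_difference_table(data, selections=sel)
        assert tbl.loc["individual", "mean_difference"] == pytest.approx(
            np.mean([10 - 8, 10 - 11, 10 - 10]))

    def test_unbalanced_rejected(self):
        data = pd.DataFrame({"shod": [1.0, 2], "wide": [1.0, np.nan]})
        with pytest.raises(ValueError):
            oc.paired_difference_table(data)

    def test_published_mean_difference_helper(self):
        assert mean_difference("linear", "peak_mcf", "insole_0") == \
            pytest.approx(240.50 - 239.06)


class TestShapiroWilk:
    def test_reference_value(self):
        """Fixed sample checked against R's shapiro.test (W = 0.978170,
        p = 0.954629)."""
        x = [2.1, 3.4, 1.9, 4.4, 2.9, 5.1, 3.3, 2.5, 4.0, 3.7]
        w, p = oc.shapiro_wilk(x)
        assert w == pytest.approx(0.978170, abs=1e-3)
        assert p == pytest.approx(0.954629, abs=1e-3)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            oc.shapiro_wilk([1.0, 1.0, 1.0, 1.0])

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            oc.shapiro_wilk([1.0, 2.0])


class TestRMAnova:
    def test_hand_computed_3x3(self):
        """SS_cond = 24 (df 2), SS_err = 4 (df 4) -> F = 12 by hand."""
        data = np.array([[1.0, 2, 3], [2, 4, 6], [3, 6, 9]])
        res = oc.rm_anova(data)
        assert res["F"] == pytest.approx(12.0, rel=1e-12)
        assert res["df"] == (2, 4)
        assert not res["degenerate"]

    def test_degenerate_zero_error_variance(self):
        data = np.tile([[1.0], [2.0], [3.0]], (1, 4))
        res = oc.rm_anova(data)
        assert res["degenerate"]

    def test_matches_pingouin_oracle(self, rng):
        import pingouin as pg
        data = rng.normal(100, 10, (6, 4)) + rng.normal(0, 5, (6, 1))
        df = pd.DataFrame(data).reset_index().melt("index", var_name="cond")
        ref = pg.rm_anova(data=df, dv="value", within="cond", subject="index")
        res = oc.rm_anova(data)
        assert res["F"] == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res["p"] == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)

    def test_vectorized_equals_scalar(self, rng):
        batch = rng.normal(0, 1, (10, 5, 7))
        vres = oc.rm_anova(batch)
        for i in range(10):
            s = oc.rm_anova(batch[i])
            assert vres["F"][i] == pytest.approx(s["F"], rel=1e-12)

    def test_missing_cells_rejected(self):
        data = np.array([[1.0, 2], [np.nan, 3]])
        with pytest.raises(ValueError):
            oc.rm_anova(data)


class TestBonferroni:
    def test_identical_pairs(self):
        x = np.array([1.0, 2, 3, 4, 5])
        tbl = oc.bonferroni_posthoc({"a": (x, x), "b": (x, x + 1)})
        assert tbl.loc["a", "mean_difference"] == 0.0
        assert tbl.loc["a", "p_adj"] == 1.0

    def test_single_comparison_equals_raw(self, rng):
        x = rng.normal(0, 1, 8)
        y = x + rng.normal(0.5, 0.3, 8)
        tbl = oc.bonferroni_posthoc({"only": (x, y)})
        assert tbl.loc["only", "p_adj"] == pytest.approx(
            tbl.loc["only", "p_raw"])

    def test_adjusted_at_least_raw_and_capped(self, rng):
        pairs = {f"c{i}": (rng.normal(0, 1, 6), rng.normal(0.2, 1, 6))
                 for i in range(7)}
        tbl = oc.bonferroni_posthoc(pairs)
        assert (tbl["p_adj"] >= tbl["p_raw"] - 1e-15).all()
        assert (tbl["p_adj"] <= 1.0).all()

    def test_ci_widens_with_comparisons(self, rng):
        x = rng.normal(0, 1, 10)
        y = x + rng.normal(0.4, 0.2, 10)
        one = oc.bonferroni_posthoc({"c": (x, y)}, n_comparisons=1)
        seven = oc.bonferroni_posthoc({"c": (x, y)}, n_comparisons=7)
        w1 = one.loc["c", "ci_high"] - one.loc["c", "ci_low"]
        w7 = seven.loc["c", "ci_high"] - seven.loc["c", "ci_low"]
        assert w7 > w1
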