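"""GTT/ITT statistics, fold changes, relative qPCR quantification and
MTT viability."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucotriage import pharmacology as ph


def tidy(groups: dict[str, dict[float, float]], n: int = 1) -> pd.DataFrame:
    rows = []
    for grp, curve in groups.items():
        for i in range(n):
            for t, g in curve.items():
                rows.append({"animal": f"{grp}-{i}", "group": grp,
                             "time_min": t, "glycemia_mg_dl": g})
    return pd.DataFrame(rows)


class TestPercentReduction:
    def test_hand_arithmetic(self):
        df = tidy({"ctrl": {0: 100, 15: 200}, "trt": {0: 100, 15: 150}})
        assert ph.percent_reduction(df, "trt", "ctrl", 15) == pytest.approx(25.0)

    def test_equal_means_give_zero(self):
        df = tidy({"ctrl": {0: 100, 15: 200}, "trt": {0: 100, 15: 200}})
        assert ph.percent_reduction(df, "trt", "ctrl", 15) == 0.0

    def test_control_vs_itself_is_identically_zero(self):
        df = tidy({"ctrl": {0: 100, 15: 321.5}})
        assert ph.percent_reduction(df, "ctrl", "ctrl", 15) == 0.0

    def test_negative_when_treated_exceeds_control(self):
        df = tidy({"ctrl": {0: 100, 15: 200}, "trt": {0: 100, 15: 250}})
        assert ph.percent_reduction(df, "trt", "ctrl", 15) == pytest.approx(-25.0)

    def test_missing_timepoint(self):
        df = tidy({"ctrl": {0: 100, 15: 200}, "trt": {0: 100}})
        with pytest.raises(ValueError):
            ph.percent_reduction(df, "trt", "ctrl", 15)


class TestGttAuc:
    def test_constant_curve_corrected_is_zero(self):
        t = np.array([0.0, 30.0, 60.0, 120.0])
        g = np.full(4, 100.0)
        assert ph.gtt_auc(t, g, baseline_corrected=True) == 0.0

    def test_constant_curve_raw_is_rectangle(self):
        t = np.array([0.0, 30.0, 60.0, 120.0])
        g = np.full(4, 100.0)
        assert ph.gtt_auc(t, g, baseline_corrected=False) == pytest.approx(12000.0)

    def test_triangle_by_hand(self):
        t = np.array([0.0, 60.0, 120.0])
        g = np.array([100.0, 200.0, 100.0])
        assert ph.gtt_auc(t, g, baseline_corrected=True) == pytest.approx(6000.0)

    def test_endpoint_interpolated_when_unsampled(self):
        # sampled to 180 only; the 120 endpoint is interpolated on [60, 180]
        t = np.array([0.0, 60.0, 180.0])
        g = np.array([100.0, 220.0, 100.0])
        # corrected excursion: 0 -> 120 -> (at 120 min) 60
        expected = (0 + 120) / 2 * 60 + (120 + 60) / 2 * 60
        assert ph.gtt_auc(t, g, baseline_corrected=True) == pytest.approx(expected)

    def test_negative_segments_contribute_negatively(self):
        t = np.array([0.0, 60.0, 120.0])
        g = np.array([100.0, 60.0, 60.0])
        auc = ph.gtt_auc(t, g, baseline_corrected=True)
        assert auc == pytest.approx(-(40 / 2 * 60 + 40 * 60))

    def test_additive_over_adjacent_windows(self, rng):
        t = np.array([0.0, 15.0, 30.0, 60.0, 120.0])
        g = 100 + rng.uniform(0, 200, size=5)
        whole = ph.gtt_auc(t, g, False, window=(0, 120))
        parts = (ph.gtt_auc(t, g, False, window=(0, 30))
                 + ph.gtt_auc(t, g, False, window=(30, 120)))
        assert whole == pytest.approx(parts)

    def test_linear_in_glycemia(self, rng):
        t = np.array([0.0, 15.0, 60.0, 120.0])
        g1 = rng.uniform(80, 300, 4)
        g2 = rng.uniform(80, 300, 4)
        a = ph.gtt_auc(t, 2 * g1 + 3 * g2, False)
        assert a == pytest.approx(2 * ph.gtt_auc(t, g1, False)
                                  + 3 * ph.gtt_auc(t, g2, False))

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            ph.gtt_auc(np.array([0.0, 60.0, 30.0]), np.full(3, 100.0))


class TestKitt:
    def test_exact_exponential_decay(self):
        t = np.array([0.0, 7.0, 14.0, 28.0])
        g = 100 * np.exp(-0.0231 * t)
        res = ph.kitt(t, g)
        assert res.valid
        assert res.t_half == pytest.approx(math.log(2) / 0.0231, rel=1e-9)
        assert res.kitt == pytest.approx(0.693 * 100 / res.t_half, rel=1e-9)
        assert res.kitt == pytest.approx(2.31, abs=5e-3)
        assert res.r_squared == pytest.approx(1.0)

    def test_flat_series_flagged_invalid(self):
        t = np.array([0.0, 7.0, 14.0, 28.0])
        res = ph.kitt(t, np.full(4, 120.0))
        assert not res.valid
        assert math.isnan(res.kitt)

    def test_rising_series_never_negative_kitt(self):
        t = np.array([0.0, 7.0, 14.0, 28.0])
        res = ph.kitt(t, 100 * np.exp(0.01 * t))
        assert not res.valid
        assert math.isnan(res.kitt)

    def test_internal_identity(self):
        t = np.array([0.0, 7.0, 14.0, 28.0])
        res = ph.kitt(t, 150 * np.exp(-0.05 * t))
        assert res.kitt == pytest.approx(0.693 * 100 / res.t_half, rel=1e-9)
        assert res.t_half == pytest.approx(math.log(2) / abs(res.slope), rel=1e-12)

    def test_group_mean_recovery_on_noisy_data(self):
        from glucotriage.synthetic_data import SimSpec, gen_itt
        df, truth = gen_itt(SimSpec(seed=5, n_per_group=8, sigma=0.02),
                            kitt_true=2.31)
        est = ph.kitt_by_group(df).loc["treated", "kitt"]
        assert est == pytest.approx(2.31, rel=0.05)

    def test_recovery_median_error_below_3pct(self):
        """Parameter recovery across the physiological Kitt range
        (0.5-5 %/min) with 2% multiplicative noise, 200 animals."""
        rng = np.random.default_rng(2129)
        t = np.array([0.0, 7.0, 14.0, 28.0])
        errors = []
        for k_true in np.linspace(0.5, 5.0, 200):
            g = 150 * np.exp(-(k_true / 100) * t) * np.exp(
                rng.normal(0, 0.02, size=4))
            errors.append(abs(ph.kitt(t, g).kitt - k_true) / k_true)
        assert np.median(errors) < 0.03


class TestFoldChange:
    def test_identity(self):
        assert ph.fold_change([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_hand_arithmetic_muscle_glycogen_scale(self):
        assert ph.fold_change([18.8], [2.0]) == pytest.approx(9.4)

    def test_empty_treated_rejected(self):
        with pytest.raises(ValueError):
            ph.fold_change([], [1.0])

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            ph.fold_change([1.0], [0.0])


class TestDdct:
    @staticmethod
    def frame(samples):
        return pd.DataFrame(
            [{"sample": f"s{i}", "group": grp, "ct_target": ct_t,
              "ct_ref": ct_r} for i, (grp, ct_t, ct_r) in enumerate(samples)])

    def test_control_centered_on_one(self):
        df = self.frame([("control", 25.0, 20.0), ("control", 25.0, 20.0)])
        out = ph.ddct(df, "control")
        np.testing.assert_allclose(out["fold"], 1.0)

    def test_one_cycle_less_doubles_expression(self):
        df = self.frame([("control", 25.0, 20.0), ("treated", 24.0, 20.0)])
        out = ph.ddct(df, "control")
        assert out.loc[out["group"] == "treated", "fold"].item() == pytest.approx(2.0)

    def test_worked_example(self):
        # control dCt 5.0, sample dCt 3.53 -> fold 2^1.47 = 2.77
        df = self.frame([("control", 25.0, 20.0), ("treated", 23.53, 20.0)])
        out = ph.ddct(df, "control")
        fold = out.loc[out["group"] == "treated", "fold"].item()
        assert fold == pytest.approx(2 ** 1.47, rel=1e-9)
        assert fold == pytest.approx(2.77, abs=0.01)

    @given(st.floats(-3, 3, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_global_ct_shift_invariance(self, shift):
        df = self.frame([("control", 25.0, 20.0), ("control", 24.6, 19.7),
                         ("treated", 23.0, 20.1), ("treated", 22.8, 19.9)])
        base = ph.ddct(df, "control")["fold"]
        shifted = df.copy()
        shifted[["ct_target", "ct_ref"]] += shift
        out = ph.ddct(shifted, "control")["fold"]
        np.testing.assert_allclose(out, base, rtol=1e-9)

    def test_empty_control_rejected(self):
        df = self.frame([("treated", 23.0, 20.0)])
        with pytest.raises(ValueError):
            ph.ddct(df, "control")

    def test_ct_range_enforced(self):
        df = self.frame([("control", 50.0, 20.0)])
        with pytest.raises(ValueError):
            ph.ddct(df, "control")


class TestViability:
    @staticmethod
    def frame(conditions):
        return pd.DataFrame(
            [{"well": f"w{i}", "condition_uM": c, "abs570": a}
             for i, (c, a) in enumerate(conditions)])

    def test_control_is_100pct(self):
        out = ph.viability(self.frame([(0.0, 1.0), (0.0, 1.0)]), 0.0)
        assert out.loc[0.0, "viability_pct"] == pytest.approx(100.0)

    def test_35pct_reduction_scale(self):
        out = ph.viability(
            self.frame([(0.0, 1.0), (0.0, 1.0), (10.0, 0.65), (10.0, 0.65)]),
            0.0)
        assert out.loc[10.0, "viability_pct"] == pytest.approx(65.0)
        assert out.loc[10.0, "reduction_pct"] == pytest.approx(35.0)

    def test_blank_wells_zero_viability(self):
        out = ph.viability(self.frame([(0.0, 1.0), (100.0, 0.0)]), 0.0)
        assert out.loc[100.0, "viability_pct"] == 0.0

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            ph.viability(self.frame([(0.0, 0.0), (10.0, 0.5)]), 0.0)


class TestValidation:
    def test_gtt_requires_time_zero(self):
        df = tidy({"ctrl": {15: 200.0}})
        with pytest.raises(ValueError, match="time-0"):
            ph.validate_gtt(df)

    def test_itt_requires_three_timepoints(self):
        df = tidy({"ctrl": {0: 100.0, 7: 90.0}})
        with pytest.raises(ValueError, match="3 timepoints"):
            ph.validate_itt(df)
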