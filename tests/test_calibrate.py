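"""Repeatability and through-origin calibration statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenoscan.calibrate import (
    ThroughOriginCalibration,
    apply_calibration,
    evaluate_repeatability,
    fit_calibration,
    mre_calibration,
    mre_repetition,
    r2_calibration,
    r2_repetition,
)


def brute_mre(num, den):
    return sum(abs(a - b) / b for a, b in zip(num, den)) / len(den)


class TestRepetitionStatistics:
    def test_identical_repetitions_zero_error(self):
        y = [100.0, 250.0, 400.0]
        assert mre_repetition(y, y) == 0.0

    def test_single_pair_forced_value(self):
        assert mre_repetition([100.0], [110.0]) == pytest.approx(0.1)

    def test_two_pair_direct_evaluation(self):
        assert mre_repetition([100.0, 200.0], [110.0, 180.0]) == pytest.approx(0.1)

    def test_normalisation_is_by_first_repetition(self):
        # the statistic is asymmetric in repetition order by definition
        assert mre_repetition([100.0], [150.0]) != mre_repetition([150.0], [100.0])

    def test_zero_first_repetition_rejected(self):
        with pytest.raises(ValueError):
            mre_repetition([0.0, 1.0], [1.0, 1.0])

    def test_r2_scale_free(self):
        y1 = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2_repetition(y1, 2 * y1) == pytest.approx(1.0)
        assert r2_repetition(y1, -y1) == pytest.approx(1.0)

    def test_r2_independent_sequences_near_zero(self):
        rng = np.random.default_rng(8)
        y1 = rng.normal(size=5000)
        y2 = rng.normal(size=5000)
        assert r2_repetition(y1, y2) < 0.01

    def test_r2_constant_sequence_undefined(self):
        with pytest.raises(ValueError):
            r2_repetition([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 200))
    def test_mre_matches_direct_summation(self, seed, n):
        rng = np.random.default_rng(seed)
        y1 = rng.uniform(1.0, 100.0, n)
        y2 = rng.uniform(1.0, 100.0, n)
        assert mre_repetition(y1, y2) == pytest.approx(brute_mre(y2, y1), abs=1e-12)
        assert mre_calibration(y1, y2) == pytest.approx(brute_mre(y1, y2), abs=1e-12)


class TestThroughOriginCalibration:
    def test_exact_proportional_data(self):
        m = fit_calibration([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert m.slope_ == pytest.approx(2.0)
        assert m.mre_ == pytest.approx(0.0)
        assert m.r2_ == pytest.approx(1.0)

    def test_closed_form_average_ratio(self):
        m = fit_calibration([1.0, 1.0], [1.0, 3.0])
        assert m.slope_ == pytest.approx(2.0)  # sum(xy)/sum(x^2) = 4/2

    def test_parameter_recovery_under_noise(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(400, 1500, 200)
        y = 1.5 * x + rng.normal(0, 5.0, 200)
        m = fit_calibration(x, y)
        assert m.slope_ == pytest.approx(1.5, rel=0.02)

    def test_residuals_orthogonal_to_x(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(1, 100, 500)
        y = 0.8 * x + rng.normal(0, 10, 500)
        m = fit_calibration(x, y)
        assert float(np.dot(x, y - m.slope_ * x)) == pytest.approx(0.0, abs=1e-7)

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 300))
    def test_slope_matches_closed_form(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 100, n)
        y = rng.uniform(0.1, 100, n)
        m = fit_calibration(x, y)
        assert m.slope_ == pytest.approx(np.dot(x, y) / np.dot(x, x), abs=1e-12)

    def test_all_zero_x_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([0.0, 0.0], [1.0, 2.0])

    def test_intercept_mode_is_ordinary_least_squares(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = 3.0 + 0.5 * x
        m = fit_calibration(x, y, fit_intercept=True)
        assert m.slope_ == pytest.approx(0.5)
        assert m.intercept_ == pytest.approx(3.0)

    def test_apply_calibration_elementwise(self):
        m = fit_calibration([1.0, 2.0], [2.0, 4.0])
        assert np.allclose(apply_calibration(m, [3.0, 0.0]), [6.0, 0.0])

    def test_fit_then_apply_reproduces_training_predictions(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 10, 50)
        y = rng.uniform(1, 10, 50)
        m = fit_calibration(x, y)
        assert np.allclose(apply_calibration(m, x), m.slope_ * x)

    def test_json_round_trip(self, tmp_path):
        m = fit_calibration([1.0, 2.0, 3.0], [2.1, 3.9, 6.2], trait="height_mm")
        m.to_json(tmp_path / "model.json")
        back = ThroughOriginCalibration.from_json(tmp_path / "model.json")
        assert back.slope_ == m.slope_
        assert back.trait == "height_mm"
        assert back.r2_ == pytest.approx(m.r2_)

    def test_sklearn_get_set_params(self):
        m = ThroughOriginCalibration(trait="h")
        assert m.get_params() == {"trait": "h", "fit_intercept": False}
        m.set_params(fit_intercept=True)
        assert m.fit_intercept


class TestCalibrationStatistics:
    def test_perfect_prediction(self):
        y = np.array([10.0, 20.0])
        assert mre_calibration(y, y) == 0.0
        assert r2_calibration(y, y + 1) == pytest.approx(1.0)  # affine invariance

    def test_single_value_forced(self):
        assert mre_calibration([110.0], [100.0]) == pytest.approx(0.1)

    def test_two_values_direct(self):
        assert mre_calibration([90.0, 210.0], [100.0, 200.0]) == pytest.approx(0.075)

    def test_affine_invariance_of_r2(self):
        rng = np.random.default_rng(12)
        y = rng.uniform(1, 100, 100)
        yh = rng.uniform(1, 100, 100)
        base = r2_calibration(yh, y)
        assert r2_calibration(3.0 * yh + 7.0, y) == pytest.approx(base, abs=1e-12)
        assert r2_calibration(yh, 0.5 * y - 2.0) == pytest.approx(base, abs=1e-12)


def _result_frame(pairs: dict, sensor="LC", parameter="lc_height"):
    rows = []
    for plot, (v1, v2) in pairs.items():
        rows.append(dict(plot_id=plot, repetition=1, sensor=sensor, parameter=parameter, value=v1))
        rows.append(dict(plot_id=plot, repetition=2, sensor=sensor, parameter=parameter, value=v2))
    return pd.DataFrame(rows)


class TestEvaluateRepeatability:
    def test_identical_repetitions_zero_mre_unit_r2(self):
        df = _result_frame({f"P{i}": (100.0 + i, 100.0 + i) for i in range(10)})
        rep = evaluate_repeatability(df)
        assert rep.loc[0, "mre_w"] == 0.0
        assert rep.loc[0, "r2_w"] == pytest.approx(1.0)
        assert rep.loc[0, "n"] == 10

    def test_constant_parameter_reports_null_r2(self):
        df = _result_frame({f"P{i}": (5.0, 5.0) for i in range(4)})
        rep = evaluate_repeatability(df)
        assert np.isnan(rep.loc[0, "r2_w"])
        assert rep.loc[0, "mre_w"] == 0.0

    def test_null_pairs_dropped_and_counted(self):
        pairs = {f"P{i}": (float(i + 1) * 10, float(i + 1) * 10 + 1) for i in range(6)}
        pairs["P9"] = (np.nan, 50.0)
        pairs["P8"] = (0.0, 50.0)  # zero first repetition excluded too
        df = _result_frame(pairs)
        rep = evaluate_repeatability(df)
        assert rep.loc[0, "n"] == 6
        assert rep.loc[0, "n_dropped"] == 2

    def test_report_row_per_group(self):
        df = pd.concat(
            [
                _result_frame({"P1": (1.0, 1.1), "P2": (2.0, 2.1)}, "LC", "lc_height"),
                _result_frame({"P1": (0.5, 0.6), "P2": (0.7, 0.8)}, "HSI", "hsi_coverage_density"),
            ],
            ignore_index=True,
        )
        rep = evaluate_repeatability(df)
        assert len(rep) == 2
        assert set(rep["sensor"]) == {"LC", "HSI"}

    def test_harvest_grouping_column(self):
        df = _result_frame({"P1": (1.0, 1.2), "P2": (2.0, 2.2), "P3": (3.0, 3.3)})
        df["harvest"] = 1
        df2 = df.copy()
        df2["harvest"] = 2
        rep = evaluate_repeatability(
            pd.concat([df, df2], ignore_index=True), ("sensor", "parameter", "harvest")
        )
        assert len(rep) == 2
        assert set(rep["harvest"]) == {1, 2}

    def test_single_pair_group_reports_null(self):
        df = _result_frame({"P1": (1.0, 1.1)})
        rep = evaluate_repeatability(df)
        assert np.isnan(rep.loc[0, "r2_w"])
        assert rep.loc[0, "n"] == 1
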