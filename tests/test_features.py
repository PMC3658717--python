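"""Per-plot statistical reductions against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoscan.core import PARAMETERS, align_stream, slice_by_position
from phenoscan.features import (
    ExtremeFractionRule,
    FeatureParams,
    GroundProfile,
    extract_plot_features,
    extreme_mean,
    ground_distance_profile,
    lc_coverage_density,
    lc_plant_height,
    lds_side_penetration,
    lds_top_height,
    lds_top_penetration,
    tof_side_penetration,
    tof_top_height,
    tof_top_penetration,
)
from phenoscan.segment import detect_plots

from conftest import make_lc_stream, make_scalar_stream


def brute_extreme_mean(values, fraction, side):
    """Independent sort-and-slice oracle."""
    v = sorted(float(x) for x in values)
    k = max(1, math.ceil(fraction * len(v)))
    sel = v[-k:] if side == "highest" else v[:k]
    return sum(sel) / len(sel)


class TestExtremeMean:
    def test_three_percent_of_hundred(self):
        rule = ExtremeFractionRule(0.03, "highest")
        assert extreme_mean(np.arange(1, 101), rule) == pytest.approx(99.0)

    def test_constant_input_any_rule(self):
        for frac in (0.01, 0.03, 0.5, 1.0):
            for side in ("highest", "lowest"):
                assert extreme_mean([7.0] * 20, ExtremeFractionRule(frac, side)) == 7.0

    def test_small_n_floors_at_one(self):
        rule = ExtremeFractionRule(0.01, "highest")
        assert extreme_mean([3.0, 9.0, 1.0], rule) == 9.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            extreme_mean([], ExtremeFractionRule(0.03))

    @settings(max_examples=200, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(1, 400),
        frac=st.floats(0.005, 1.0),
        side=st.sampled_from(["highest", "lowest"]),
    )
    def test_matches_brute_force_oracle(self, seed, n, frac, side):
        values = np.random.default_rng(seed).normal(size=n) * 100
        rule = ExtremeFractionRule(frac, side)
        assert extreme_mean(values, rule) == pytest.approx(
            brute_extreme_mean(values, frac, side), abs=1e-12
        )


class TestLcCoverageDensity:
    def test_all_interrupted(self):
        assert lc_coverage_density(make_lc_stream(np.ones((5, 288)))) == 1.0

    def test_none_interrupted(self):
        assert lc_coverage_density(make_lc_stream(np.zeros((5, 288)))) == 0.0

    def test_quarter_interrupted_two_columns(self):
        cols = np.zeros((2, 288))
        cols[0, :144] = 1
        assert lc_coverage_density(make_lc_stream(cols)) == pytest.approx(0.25)

    def test_empty_slice_rejected(self):
        with pytest.raises(ValueError):
            lc_coverage_density(make_lc_stream(np.zeros((0, 288))))


class TestGroundDistanceProfile:
    def test_constant_distance_everywhere(self):
        s = make_scalar_stream(np.full(4000, 200.0), positions=np.arange(4000), name="LDS3")
        prof = ground_distance_profile(s, 0, 4000)
        assert len(prof.ground_mm) == 40
        assert np.allclose(prof.ground_mm, 200.0)

    def test_outliers_dominate_max_side_average(self):
        """3% high outliers (true ground) override the 97% shorter plant hits."""
        rng = np.random.default_rng(0)
        n = 1000
        d = np.full(n, 250.0)
        hi = rng.choice(n, size=30, replace=False)
        d[hi] = 260.0
        s = make_scalar_stream(d, positions=np.linspace(0, 99, n).astype(int), name="LDS3")
        prof = ground_distance_profile(s, 0, 100)
        assert prof.ground_mm[0] == pytest.approx(260.0)

    def test_short_trailing_increment_merges(self):
        # 4030 mm extent: trailing 30 mm holds < 10 samples at 0.1 samples/mm
        pos = np.arange(0, 4030, 12)
        s = make_scalar_stream(np.full(len(pos), 200.0), positions=pos, name="LDS3")
        prof = ground_distance_profile(s, 0, 4030)
        assert len(prof.ground_mm) == 40  # merged, not 41

    def test_empty_increment_interpolated(self, caplog):
        pos = np.concatenate([np.arange(0, 100), np.arange(200, 300)])
        d = np.concatenate([np.full(100, 190.0), np.full(100, 210.0)])
        s = make_scalar_stream(d, positions=pos, name="LDS3")
        with caplog.at_level("WARNING"):
            prof = ground_distance_profile(s, 0, 300)
        assert prof.ground_mm[1] == pytest.approx(200.0)
        assert "empty ground increments" in caplog.text


class TestLcPlantHeight:
    def test_single_reading_formula(self):
        cols = np.zeros((1, 288))
        cols[0, 280] = 1
        s = make_lc_stream(cols)
        prof = GroundProfile(np.array([0]), np.array([200.0]))
        assert lc_plant_height(s, None, prof) == pytest.approx(280 * 2.5 + 200.0)

    def test_ground_distance_additivity(self):
        cols = np.zeros((3, 288))
        cols[:, 100] = 1
        s = make_lc_stream(cols)
        h1 = lc_plant_height(s, None, GroundProfile(np.array([0]), np.array([200.0])))
        h2 = lc_plant_height(s, None, GroundProfile(np.array([0]), np.array([400.0])))
        assert h2 - h1 == pytest.approx(200.0)

    def test_upper_curtain_extends_stacked_index(self):
        lower_cols = np.zeros((1, 288))
        lower_cols[0, :50] = 1  # 50 readings -> N=51, k=1
        lower = make_lc_stream(lower_cols)
        upper_cols = np.zeros((1, 288))
        upper_cols[0, 0] = 1  # stacked index 288
        upper = make_lc_stream(upper_cols, name="LC_upper")
        prof = GroundProfile(np.array([0]), np.array([200.0]))
        h = lc_plant_height(lower, upper, prof)
        assert h == pytest.approx(288 * 2.5 + 200.0)  # single highest reading

    def test_no_canopy_raises(self):
        s = make_lc_stream(np.zeros((5, 288)))
        prof = GroundProfile(np.array([0]), np.array([200.0]))
        with pytest.raises(ValueError, match="no canopy"):
            lc_plant_height(s, None, prof)

    def test_zero_noise_recovery_within_quantisation(self, zero_noise_sim):
        plan, truths, recordings = zero_noise_sim
        rec = recordings[0]
        segs = detect_plots(rec, plan.plots_per_row["R01"])
        records = {
            r.parameter: r.value
            for r in extract_plot_features(segs[0], rec)
        }
        # pooled 1%-highest rule reaches at most one barrier pitch plus the
        # 1%-deep pool below the true canopy top
        assert abs(records["lc_height"] - truths[0].true_height_mm) < 10.0


class TestDistanceStatistics:
    def test_lds_top_height_forced_selection(self):
        d = np.concatenate([np.full(97, 500.0), np.full(3, 1500.0)])
        assert lds_top_height(d) == pytest.approx(1000.0)

    def test_constant_distances_zero_height_and_penetration(self):
        d = np.full(50, 640.0)
        assert lds_top_height(d) == 0.0
        assert lds_top_penetration(d) == 0.0

    def test_penetration_brute_force_1_to_100(self):
        d = np.arange(1, 101, dtype=float)
        assert lds_top_penetration(d) == pytest.approx(50.5 - 2.0)

    def test_side_penetration_is_plain_mean(self):
        assert lds_side_penetration(np.arange(1, 101)) == pytest.approx(50.5)
        with pytest.raises(ValueError):
            lds_side_penetration([])

    def test_shift_invariance_of_differences(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(300, 1500, 500)
        for stat in (lds_top_height, lds_top_penetration):
            assert stat(d + 123.0) == pytest.approx(stat(d), abs=1e-9)


class TestTofStatistics:
    def test_forced_pixel_selection(self):
        frame = np.full((1, 50, 64), 500.0)
        flat = frame.reshape(-1)
        k = math.ceil(0.03 * flat.size)
        frame.reshape(-1)[:k] = 1500.0
        assert tof_top_height(frame) == pytest.approx(1000.0)

    def test_duplicated_frames_leave_statistics_unchanged(self):
        rng = np.random.default_rng(2)
        one = rng.uniform(300, 900, (1, 50, 64))
        two = np.concatenate([one, one])
        # fractions scale with N, so duplication cannot move a percentile mean
        assert tof_top_height(two) == pytest.approx(tof_top_height(one))
        assert tof_top_penetration(two) == pytest.approx(tof_top_penetration(one))

    def test_constant_frames_zero_penetration(self):
        assert tof_top_penetration(np.full((3, 50, 64), 777.0)) == 0.0
        assert tof_side_penetration(np.full((3, 50, 64), 777.0)) == 777.0

    def test_pooled_tof_equals_lds_on_constant_frames(self):
        """Frames that replicate the scalar samples give identical statistics.

        N = 100 makes the 3% selection exact, so the count rule scales
        proportionally between the scalar and the pooled pixel multiset."""
        rng = np.random.default_rng(3)
        scalars = rng.uniform(300, 1500, 100)
        frames = np.repeat(scalars, 50 * 64).reshape(100, 50, 64)
        assert tof_top_height(frames) == pytest.approx(lds_top_height(scalars))
        assert tof_top_penetration(frames) == pytest.approx(lds_top_penetration(scalars))
        assert tof_side_penetration(frames) == pytest.approx(lds_side_penetration(scalars))


class TestExtractPlotFeatures:
    def test_full_parameter_set_on_clean_plot(self, zero_noise_sim):
        plan, truths, recordings = zero_noise_sim
        rec = recordings[0]
        segs = detect_plots(rec, plan.plots_per_row["R01"])
        records = extract_plot_features(segs[1], rec, repetition=2)
        assert [r.parameter for r in records] == list(PARAMETERS)
        assert all(np.isfinite(r.value) for r in records)
        assert all(r.repetition == 2 for r in records)

    def test_missing_stream_degrades_to_nan(self, zero_noise_sim):
        plan, truths, recordings = zero_noise_sim
        rec = recordings[0]
        segs = detect_plots(rec, plan.plots_per_row["R01"])
        crippled = type(rec)(
            rec.row_id, rec.start, rec.end,
            {k: v for k, v in rec.streams.items() if not k.startswith("ToF")},
        )
        records = {r.parameter: r.value for r in extract_plot_features(segs[0], crippled)}
        assert np.isnan(records["tof1_height"])
        assert np.isnan(records["tof2_penetration_side"])
        assert np.isfinite(records["lc_height"])

    def test_identical_passes_produce_identical_features(self, zero_noise_cfg, zero_noise_sim):
        from phenoscan.simulate import simulate_pass

        plan, truths, recordings = zero_noise_sim
        again = simulate_pass(plan, truths, zero_noise_cfg)
        segs = detect_plots(recordings[0], plan.plots_per_row["R01"])
        a = extract_plot_features(segs[0], recordings[0])
        b = extract_plot_features(segs[0], again[0])
        assert [(r.parameter, r.value) for r in a] == [(r.parameter, r.value) for r in b]
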