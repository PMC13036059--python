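import numpy as np
import pytest

from thermorun.physio import build_protocol
from thermorun.fuse import (SensorTrace, resample_to_timeline, interpolate_missing,
                            savgol_smooth, butterworth_lowpass, rolling_median,
                            label_phases, ramp_exclusions, aggregate_stage,
                            cohort_median_series, stage_table)

from oracles import naive_rolling_median, two_point_interp


class TestResample:
    def test_identity_on_same_times(self):
        t = np.arange(10.0)
        v = np.sin(t)
        assert np.allclose(resample_to_timeline(t, v, t), v)

    def test_exact_on_linear_ramp(self):
        t = np.arange(0.0, 10.0)          # 1 Hz
        v = 3.0 + 0.5 * t
        tq = np.arange(0.0, 9.0, 1 / 30)  # 30 Hz query
        assert np.allclose(resample_to_timeline(t, v, tq), 3.0 + 0.5 * tq, atol=1e-12)

    def test_matches_two_point_oracle(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 100, size=40))
        t += np.arange(40) * 1e-6
        v = rng.normal(size=40)
        tq = rng.uniform(-10, 110, size=200)
        assert np.allclose(resample_to_timeline(t, v, tq),
                           two_point_interp(tq, t, v), atol=1e-12)

    def test_endpoints_held(self):
        out = resample_to_timeline([1.0, 2.0], [5.0, 7.0], [-1.0, 3.0])
        assert out.tolist() == [5.0, 7.0]

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            resample_to_timeline([1.0], [2.0], [1.5])


class TestInterpolateMissing:
    def test_all_defined_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(interpolate_missing(v), v)

    def test_single_interior_gap(self):
        v = np.array([30.0, np.nan, 32.0])
        assert interpolate_missing(v)[1] == pytest.approx(31.0)

    def test_leading_trailing_nearest(self):
        v = np.array([np.nan, 5.0, np.nan])
        assert interpolate_missing(v).tolist() == [5.0, 5.0, 5.0]

    def test_random_gaps_match_naive_oracle(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=60)
        v[rng.random(60) < 0.3] = np.nan
        v[0] = 1.0
        v[-1] = 2.0
        got = interpolate_missing(v)
        # naive: for each gap, linear between the neighbouring defined values
        idx = np.flatnonzero(np.isfinite(v))
        expected = np.interp(np.arange(60), idx, v[idx])
        assert np.allclose(got, expected, atol=1e-12)


class TestSavgol:
    def test_exact_on_cubic(self):
        t = np.linspace(0, 1, 400)
        v = 1.0 - 2.0 * t + 3.0 * t ** 2 - 0.5 * t ** 3
        out = savgol_smooth(v, window=151, polyorder=3)
        assert np.max(np.abs(out - v)) < 1e-8

    def test_constant_unchanged(self):
        out = savgol_smooth(np.full(200, 7.0), window=151)
        assert np.allclose(out, 7.0)

    def test_variance_reduction_on_noise(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal(2000)
        out = savgol_smooth(v, window=151)
        assert out.var() < v.var()

    def test_window_validation(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(200), window=150)
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(100), window=151)


class TestButterworth:
    def test_dc_gain_one(self):
        out = butterworth_lowpass(np.full(500, 3.7))
        assert np.max(np.abs(out - 3.7)) < 1e-9

    def test_high_frequency_attenuation(self):
        t = np.arange(4000)
        v = np.sin(2 * np.pi * 0.25 * t)    # far above the 0.02 cyc/sample cutoff
        out = butterworth_lowpass(v)
        assert np.max(np.abs(out[500:-500])) < 1.0 / 20.0

    def test_linear_trend_preserved(self):
        t = np.arange(3000, dtype=float)
        v = 0.01 * t + 5.0
        out = butterworth_lowpass(v)
        mid = slice(600, 2400)
        assert np.max(np.abs(out[mid] - v[mid]) / np.abs(v[mid])) < 0.01

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(np.ones(100), cutoff_normalized=1.5)


class TestRollingMedian:
    def test_constant(self):
        assert np.allclose(rolling_median(np.full(100, 2.0), window=9), 2.0)

    def test_spike_removed(self):
        v = np.full(50, 1.0)
        v[25] = 99.0
        out = rolling_median(v, window=5)
        assert out[25] == 1.0

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=120)
        for w in (5, 21, 51):
            assert np.allclose(rolling_median(v, window=w),
                               naive_rolling_median(v, w), atol=1e-12)

    def test_monotone_preserved(self):
        v = np.linspace(0, 10, 200)
        out = rolling_median(v, window=21)
        assert np.all(np.diff(out) >= 0)


class TestPhasesAndStages:
    def test_fh_sh_equal_halves(self):
        for sid in ("T1", "T2", "T3"):
            ph = label_phases(build_protocol(sid, 12.2))
            assert ph["FH"] == (600.0, 1680.0)
            assert ph["SH"] == (1680.0, 2760.0)
            assert ph["FH"][1] - ph["FH"][0] == pytest.approx(18 * 60.0)

    def test_phases_tile_session(self):
        ph = label_phases(build_protocol("T2", 12.0))
        spans = sorted(ph.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 == pytest.approx(b0)
        assert spans[0][0] == 0.0 and spans[-1][1] == pytest.approx(2940.0)

    def test_one_exclusion_per_velocity_change(self):
        p = build_protocol("T2", 12.0)
        excl = ramp_exclusions(p)
        changes = 1  # initial acceleration into warm-up
        v = p.phases[0].velocity
        for ph in p.phases[1:]:
            if abs(ph.velocity - v) > 1e-9:
                changes += 1
            v = ph.velocity
        assert len(excl) == changes + 1   # + final deceleration

    def test_constant_series_stage_mean(self):
        p = build_protocol("T1", 12.0)
        t = np.arange(0.0, 2941.0)
        out = aggregate_stage(t, {"x": np.full(t.size, 4.2)}, p)
        assert all(s.values["x"] == pytest.approx(4.2) for s in out)
        assert [s.stage_id for s in out] == [ph.name for ph in p.phases]

    def test_ramped_series_hand_computed_window(self):
        p = build_protocol("T1", 12.0)
        t = np.arange(0.0, 2941.0)
        v = 0.001 * t
        out = aggregate_stage(t, {"x": v}, p)
        wu = out[0]
        # final 5 s of the warm-up, minus the samples inside the deceleration
        # ramp that starts 2 s (margin) before the commanded velocity change
        sel = (t > 595.0) & (t <= 600.0) & (t < 598.0)
        expected = v[sel].mean()
        assert wu.values["x"] == pytest.approx(expected, abs=1e-9)

    def test_stage_inside_ramp_invalid(self):
        p = build_protocol("T1", 12.0)
        # sparse sampling that leaves no samples in the final 5 s windows
        t = np.arange(0.0, 2941.0, 300.0)
        out = aggregate_stage(t, {"x": np.ones(t.size)}, p)
        assert any(not s.valid for s in out)

    def test_stage_table_roundtrip(self):
        p = build_protocol("T1", 12.0)
        t = np.arange(0.0, 2941.0)
        df = stage_table(aggregate_stage(t, {"x": np.ones(t.size)}, p))
        assert list(df["phase"]) == ["WU", "SH", "REC"] or "WU" in set(df["phase"])
        assert {"stage_id", "phase", "valid", "x"} <= set(df.columns)


class TestCohortMedian:
    def test_identical_participants_identity(self):
        v = np.tile(np.arange(10.0), (5, 1))
        assert np.array_equal(cohort_median_series(v), np.arange(10.0))

    def test_robust_to_outlier(self):
        panel = np.array([[1.0], [2.0], [100.0]])
        assert cohort_median_series(panel)[0] == 2.0

    def test_matches_nanmedian_oracle(self):
        rng = np.random.default_rng(4)
        panel = rng.normal(size=(7, 30))
        panel[rng.random(panel.shape) < 0.2] = np.nan
        got = cohort_median_series(panel)
        for j in range(30):
            col = panel[:, j]
            col = col[np.isfinite(col)]
            if col.size:
                assert got[j] == pytest.approx(np.median(col), abs=1e-12)
            else:
                assert np.isnan(got[j])


class TestSensorTrace:
    def test_invariants(self):
        n = 10
        with pytest.raises(ValueError, match="strictly increasing"):
            SensorTrace(np.zeros(n), np.ones(n), np.ones(n), np.ones(n),
                        np.ones(n), np.full(n, np.nan), np.ones(n), np.ones(n))
        with pytest.raises(ValueError, match="RPE"):
            SensorTrace(np.arange(n), np.ones(n), np.ones(n), np.ones(n),
                        np.ones(n), np.full(n, 25.0), np.ones(n), np.ones(n))
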