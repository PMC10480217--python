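"""Sliding biomarker, awake threshold, the ramp controller (against a
brute-force reference), stage-resolved ON time and the quarter analysis."""

import numpy as np
import pytest

from pallidal_sleep import adbs
from pallidal_sleep.adbs import BiomarkerSeries, ControllerConfig

from conftest import make_hypnogram
from pallidal_sleep import staging


def series_from(beta):
    beta = np.asarray(beta, float)
    return BiomarkerSeries(times=0.5 * np.arange(beta.size), beta=beta)


def reference_controller(beta, threshold, v_max=3.0, ramp=0.4, dt=0.5):
    """Step-by-step reference simulator (independent oracle)."""
    amp, out = 0.0, [0.0]
    for b in beta[1:]:
        amp += ramp * dt if b > threshold else -ramp * dt
        amp = min(v_max, max(0.0, amp))
        out.append(amp)
    return np.array(out)


class TestSlidingBeta:
    def test_window_count_closed_form(self, rng):
        fs = 500.0
        x = rng.standard_normal(int(700 * fs))
        series = adbs.sliding_beta(x, fs)
        assert series.beta.size == 1 + int((700 - 5) / 0.5) == 1391

    def test_stationary_signal_gives_flat_series(self, rng):
        x = rng.standard_normal(int(60 * 500))
        series = adbs.sliding_beta(x, 500.0)
        assert series.beta.std() / series.beta.mean() < 0.25

    def test_smoothing_preserves_mass(self):
        from scipy.ndimage import gaussian_filter1d

        impulse = np.zeros(101)
        impulse[50] = 1.0
        sm = gaussian_filter1d(impulse, adbs.SMOOTH_SIGMA)
        assert sm.sum() == pytest.approx(1.0)
        assert sm.max() < 1.0

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            adbs.sliding_beta(np.zeros(100), 500.0)


class TestAwakeThreshold:
    def test_median_of_three(self):
        assert adbs.awake_threshold(series_from([1.0, 2.0, 3.0])) == 2.0

    def test_all_equal(self):
        assert adbs.awake_threshold(series_from([1.5] * 10)) == 1.5

    def test_standard_normal_median_near_zero(self, rng):
        assert abs(adbs.awake_threshold(rng.standard_normal(10_000))) < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            adbs.awake_threshold(np.array([]))


class TestController:
    def test_full_ramp_takes_7_5_seconds(self):
        series = series_from(np.full(60, 10.0))
        trace = adbs.simulate_controller(series, ControllerConfig(threshold=1.0))
        reach = series.times[np.argmax(trace.amplitude >= 3.0)]
        assert reach == pytest.approx(3.0 / 0.4)  # 7.5 s
        assert np.all(trace.amplitude[series.times >= 7.5] == 3.0)

    def test_below_threshold_never_stimulates(self):
        series = series_from(np.zeros(100))
        trace = adbs.simulate_controller(series, ControllerConfig(threshold=1.0))
        assert np.all(trace.amplitude == 0.0)
        assert not trace.stim_on.any()

    def test_square_wave_matches_reference(self):
        beta = np.tile(np.r_[np.full(20, 2.0), np.full(20, 0.0)], 10)
        series = series_from(beta)
        trace = adbs.simulate_controller(series, ControllerConfig(threshold=1.0))
        assert np.allclose(trace.amplitude, reference_controller(beta, 1.0))
        # per full cycle: 10 s above + 7.5 s decay ramp of ON time
        on_per_cycle = trace.stim_on[40:80].sum() * 0.5
        assert on_per_cycle == pytest.approx(10.0 + 3.0 / 0.4, abs=0.5)

    def test_random_series_match_reference(self, rng):
        for _ in range(25):
            beta = rng.standard_normal(200).cumsum()
            thr = float(np.median(beta))
            trace = adbs.simulate_controller(series_from(beta), ControllerConfig(threshold=thr))
            assert np.allclose(trace.amplitude, reference_controller(beta, thr))

    def test_slew_rate_and_clipping_invariants(self, rng):
        for _ in range(200):
            beta = rng.standard_normal(300).cumsum()
            cfg = ControllerConfig(threshold=float(rng.normal()))
            trace = adbs.simulate_controller(series_from(beta), cfg)
            assert np.all(trace.amplitude >= cfg.v_min)
            assert np.all(trace.amplitude <= cfg.v_max)
            assert np.max(np.abs(np.diff(trace.amplitude))) <= cfg.ramp_rate * 0.5 + 1e-12

    def test_on_time_monotone_in_threshold(self, rng):
        for _ in range(30):
            beta = rng.standard_normal(400).cumsum()
            prev = np.inf
            for q in (10, 30, 50, 70, 90):
                thr = float(np.percentile(beta, q))
                trace = adbs.simulate_controller(series_from(beta), ControllerConfig(threshold=thr))
                on = trace.stim_on.sum()
                assert on <= prev
                prev = on


class TestStageOnTime:
    def test_all_on_and_alternating(self):
        h = staging.hypnogram_as_consensus(make_hypnogram(["N2", "N2"]))
        times = 0.5 * np.arange(120)
        trace = adbs.StimulationTrace(times, np.ones(120), np.ones(120), np.ones(120, bool), 0.5)
        assert adbs.stim_on_fraction(trace, h, "NREM") == 100.0
        alt = adbs.StimulationTrace(times, np.ones(120), np.ones(120),
                                    np.arange(120) % 2 == 0, 0.5)
        assert adbs.stim_on_fraction(alt, h, "NREM") == 50.0

    def test_absent_stage_is_missing(self):
        h = staging.hypnogram_as_consensus(make_hypnogram(["N2"]))
        trace = adbs.StimulationTrace(0.5 * np.arange(60), np.ones(60), np.ones(60),
                                      np.ones(60, bool), 0.5)
        assert np.isnan(adbs.stim_on_fraction(trace, h, "R"))


class TestQuarters:
    def test_quarters_split_equally(self):
        vals = np.arange(100.0)
        q = adbs.quarter_values(vals, np.ones(100, bool))
        assert np.allclose(q, [12.0, 37.0, 62.0, 87.0])
        assert all((np.arange(5) * 100 // 4)[1:] - (np.arange(5) * 100 // 4)[:-1] == 25)

    def test_identical_quarters_give_p_one(self):
        m = np.ones((5, 4))
        res = adbs.quarter_analysis(m)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_strictly_increasing_quarters_maximal_statistic(self):
        m = np.tile(np.arange(4.0), (6, 1)) + np.random.default_rng(0).normal(0, 1e-6, (6, 4))
        res = adbs.quarter_analysis(m)
        # maximal Friedman statistic for n blocks, k treatments is n(k-1)
        assert res.statistic == pytest.approx(6 * 3, rel=1e-6)
        assert res.p_value < 0.01
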