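"""Morlet envelopes, cohort thresholding, burst detection (with a naive
sample-by-sample reference), and burst statistics."""

import numpy as np
import pytest

from pallidal_sleep import bursts
from pallidal_sleep import synthetic as syn
from pallidal_sleep.bursts import BurstEvent


def naive_detect(env, threshold, min_dur=0.1, rate=200.0):
    """Sample-by-sample reference burst detector (independent oracle)."""
    events, run = [], 0
    for i, v in enumerate(list(env) + [threshold]):  # sentinel ends last run
        if v > threshold:
            run += 1
            continue
        if run / rate >= min_dur - 1e-12:
            i0 = i - run
            auc = sum(env[j] - threshold for j in range(i0, i)) / rate
            events.append((i0 / rate, run / rate, auc))
        run = 0
    return events


class TestEnvelope:
    def test_constant_sinusoid_gives_flat_envelope(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 20.0 * t)
        env = bursts.morlet_envelope(x, fs, 20.0, zscore=False)
        core = env[400:-400]
        assert core.std() / core.mean() < 0.05

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="z-score"):
            bursts.morlet_envelope(np.zeros(4000), 500.0, 20.0)

    def test_center_freq_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bursts.morlet_envelope(np.random.default_rng(0).standard_normal(4000), 500.0, 120.0)

    def test_envelope_peak_near_injected_burst_center(self, nrem_only_hypnogram):
        prof = syn.LfpProfile(
            burst_rate_by_stage={s: (1 / 30 if s == "N2" else 0.0) for s in syn.STAGES},
            burst_duration_dist={s: (np.log(1.0), 1e-6) for s in syn.STAGES},
            burst_amplitude=1.5,
            theta_power_by_stage={s: 0.0 for s in syn.STAGES},
        )
        hits = total = 0
        for seed in range(8):
            rec, truth = syn.generate_lfp(nrem_only_hypnogram, prof, seed)
            if not truth.true_burst_events:
                continue
            env = bursts.morlet_envelope(rec.data[0], rec.sample_rate, 20.0, zscore=False)
            for start, dur, _ in truth.true_burst_events:
                total += 1
                center = start + dur / 2
                lo, hi = int((center - 0.6) * 200), int((center + 0.6) * 200)
                lo, hi = max(lo, 0), min(hi, env.size)
                peak_t = (lo + np.argmax(env[lo:hi])) / 200.0
                hits += abs(peak_t - center) <= 0.025
        assert total > 0 and hits / total >= 0.8


class TestThreshold:
    def test_standard_normal_percentile(self, rng):
        env = rng.standard_normal((1, 400_000))
        thr = bursts.cohort_threshold([env], q=75.0)
        assert thr[0] == pytest.approx(0.674, abs=0.01)

    def test_all_equal_values(self):
        env = np.full((1, 100), 1.3)
        thr = bursts.cohort_threshold([env])
        assert thr[0] == 1.3
        assert bursts.detect_bursts(env[0], thr[0]) == []

    def test_duplication_invariance(self, rng):
        env = rng.standard_normal((2, 5000))
        once = bursts.cohort_threshold([env])
        twice = bursts.cohort_threshold([env, env])
        assert np.allclose(once, twice)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bursts.cohort_threshold([])


class TestDetection:
    def test_19_samples_below_minimum(self):
        env = np.zeros(200)
        env[50:69] = 2.0  # 19 samples = 0.095 s
        assert bursts.detect_bursts(env, 1.0) == []

    def test_20_samples_is_inclusive_boundary(self):
        env = np.zeros(200)
        env[50:70] = 2.0  # 20 samples = 0.100 s
        (ev,) = bursts.detect_bursts(env, 1.0)
        assert ev.duration == pytest.approx(0.1)

    def test_rectangular_burst_auc_closed_form(self):
        env = np.zeros(400)
        env[100:200] = 2.0  # 0.5 s at threshold+1
        (ev,) = bursts.detect_bursts(env, 1.0)
        assert ev.auc_amplitude == pytest.approx(0.5)
        assert ev.duration == pytest.approx(0.5)
        hist = bursts.burst_stats([ev], 2.0).duration_hist
        assert hist[2] == 1.0  # [0.40, 0.55) bin

    def test_matches_naive_reference_on_random_envelopes(self, rng):
        """Vectorized detector == sample-by-sample oracle on 1,000 envelopes."""
        for _ in range(1000):
            n = int(rng.integers(30, 400))
            env = rng.standard_normal(n).cumsum() / 3.0  # correlated wandering
            thr = float(rng.normal(0, 1))
            fast = bursts.detect_bursts(env, thr)
            slow = naive_detect(env, thr)
            assert len(fast) == len(slow)
            for f, (s0, sdur, sauc) in zip(fast, slow):
                assert f.start == pytest.approx(s0)
                assert f.duration == pytest.approx(sdur)
                assert f.auc_amplitude == pytest.approx(sauc)

    def test_threshold_monotonicity(self, rng):
        """Raising the threshold never increases supra-threshold or burst time.

        (Burst *count* is not monotone: a long run can split into several
        shorter ones; only the time totals shrink monotonically.)
        """
        for _ in range(50):
            env = rng.standard_normal(2000).cumsum() / 5.0
            prev_supra, prev_burst_time = np.inf, np.inf
            for thr in np.linspace(env.min(), env.max(), 9):
                ev = bursts.detect_bursts(env, float(thr))
                burst_time = sum(e.duration for e in ev)
                supra = np.sum(env > thr) / 200.0
                assert supra <= prev_supra + 1e-12
                assert burst_time <= prev_burst_time + 1e-12
                prev_supra, prev_burst_time = supra, burst_time


class TestStats:
    def test_no_events(self):
        st = bursts.burst_stats([], 20.0)
        assert st.density == 0.0
        assert st.duration_hist is None

    def test_density(self):
        events = [BurstEvent(i, 0.2, 0.1, 20.0) for i in range(10)]
        assert bursts.burst_stats(events, 20.0).density == pytest.approx(0.5)

    def test_histogram_sums_to_one(self, rng):
        events = [
            BurstEvent(0.0, float(d), 0.1, 20.0)
            for d in rng.uniform(0.1, 1.2, size=50)
        ]
        st = bursts.burst_stats(events, 100.0)
        assert st.duration_hist.sum() == pytest.approx(1.0)

    def test_bin_average_idempotent_on_identical_bins(self):
        events = [BurstEvent(0.0, 0.3, 0.2, 20.0)]
        per_bin = [bursts.burst_stats(events, 10.0) for _ in range(18)]
        avg = bursts.average_over_bins(per_bin)
        assert avg.mean_duration == pytest.approx(0.3)
        assert avg.density == pytest.approx(0.1)
        assert avg.n_bins_averaged == 18
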