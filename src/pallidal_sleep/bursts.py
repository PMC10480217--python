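"""Per-Hz beta-burst analysis.

The signal is downsampled to 200 Hz and decomposed with 10-cycle complex
Morlet wavelets at 18 integer center frequencies (13-30 Hz). The wavelet
amplitude is z-scored per recording; a cohort-level threshold is the 75th
percentile of the pooled z-scored amplitude distribution (per frequency
bin, across all hemispheres/subjects). A burst is a maximal supra-threshold
run lasting at least 0.1 s; it is characterized by its duration, the area
between the envelope and the threshold (AUC, z*s), and contributes to a
per-second density. Final statistics are the unweighted average of the 18
per-frequency iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

BURST_RATE = 200.0
BETA_BIN_FREQS = tuple(float(f) for f in range(13, 31))  # 18 bins, 13..30 Hz
MIN_BURST_S = 0.1
#: burst-duration histogram edges: six 0.15-s windows from 0.1 s, last open
DURATION_BIN_EDGES = (0.10, 0.25, 0.40, 0.55, 0.70, 0.85, np.inf)


def resample_for_bursts(samples: np.ndarray, sample_rate: float) -> np.ndarray:
    """Anti-aliased resample to the 200 Hz burst-analysis rate."""
    if sample_rate < 2 * BURST_RATE:
        raise ValueError(f"input rate {sample_rate} Hz must be >= {2 * BURST_RATE} Hz")
    if sample_rate == BURST_RATE:
        return np.asarray(samples, float)
    ratio = Fraction(int(round(BURST_RATE * 1000)), int(round(sample_rate * 1000)))
    return sps.resample_poly(np.asarray(samples, float), ratio.numerator, ratio.denominator)


def _morlet_amplitude(x200: np.ndarray, freqs: np.ndarray, n_cycles: float) -> np.ndarray:
    from mne.time_frequency import tfr_array_morlet

    out = tfr_array_morlet(
        x200[None, None, :], sfreq=BURST_RATE, freqs=freqs, n_cycles=n_cycles,
        output="complex", verbose="error",
    )
    return np.abs(out[0, 0])  # (n_freqs, n_times)


def morlet_envelope(
    samples: np.ndarray,
    sample_rate: float,
    center_freq: float,
    n_cycles: float = 10.0,
    zscore: bool = True,
) -> np.ndarray:
    """Z-scored Morlet amplitude envelope at one center frequency (200 Hz out)."""
    return envelope_bank(samples, sample_rate, [center_freq], n_cycles, zscore)[0]


def envelope_bank(
    samples: np.ndarray,
    sample_rate: float,
    freqs=BETA_BIN_FREQS,
    n_cycles: float = 10.0,
    zscore: bool = True,
) -> np.ndarray:
    """Morlet amplitude envelopes at several frequencies, ``(n_freqs, n_times)``.

    Envelopes are z-scored per recording and per frequency bin; a flat
    (zero-variance) envelope cannot be z-scored and raises.
    """
    freqs = np.asarray(freqs, float)
    if np.any(freqs >= BURST_RATE / 2):
        raise ValueError("center frequency at or above the 100 Hz Nyquist of 200 Hz data")
    x200 = resample_for_bursts(samples, sample_rate)
    amp = _morlet_amplitude(x200, freqs, n_cycles)
    if zscore:
        sd = amp.std(axis=-1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("degenerate (constant) envelope: cannot z-score")
        amp = (amp - amp.mean(axis=-1, keepdims=True)) / sd
    return amp


def cohort_threshold(pooled_envelopes, q: float = 75.0) -> np.ndarray:
    """Per-frequency-bin percentile of the pooled amplitude distribution.

    *pooled_envelopes* is a sequence of ``(n_freqs, n_times_i)`` arrays (one
    per hemisphere/recording); the percentile is taken over the
    concatenation along time.
    """
    arrays = [np.atleast_2d(np.asarray(e, float)) for e in pooled_envelopes]
    if not arrays or sum(a.shape[-1] for a in arrays) == 0:
        raise ValueError("empty envelope pool")
    pooled = np.concatenate(arrays, axis=-1)
    return np.percentile(pooled, q, axis=-1)


@dataclass(frozen=True)
class BurstEvent:
    start: float  # s
    duration: float  # s
    auc_amplitude: float  # z*s above threshold
    frequency_bin: float  # Hz


def detect_bursts(
    envelope: np.ndarray,
    threshold: float,
    min_dur: float = MIN_BURST_S,
    rate: float = BURST_RATE,
    frequency_bin: float = np.nan,
) -> list[BurstEvent]:
    """Maximal supra-threshold runs of the envelope lasting at least *min_dur*.

    Duration is the run length in samples divided by *rate* (a 20-sample run
    at 200 Hz is exactly the 0.1-s minimum, inclusive); AUC is the Riemann
    sum of (envelope - threshold) over the run.
    """
    env = np.asarray(envelope, float)
    above = env > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, env.size]
    min_samples = int(round(min_dur * rate))
    events = []
    dt = 1.0 / rate
    for i0, i1 in zip(starts, ends):
        if i1 - i0 < min_samples:
            continue
        events.append(
            BurstEvent(
                start=i0 * dt,
                duration=(i1 - i0) * dt,
                auc_amplitude=float((env[i0:i1] - threshold).sum() * dt),
                frequency_bin=frequency_bin,
            )
        )
    return events


@dataclass
class BurstStats:
    """Burst summary for one recording (optionally averaged over bins)."""

    duration_hist: np.ndarray | None  # 6 proportions, sums to 1, None if no bursts
    mean_duration: float
    mean_auc: float
    density: float  # bursts / s
    n_bins_averaged: int = 1


def burst_stats(events: list[BurstEvent], recording_duration: float) -> BurstStats:
    """Histogram/duration/AUC/density summary of one frequency bin's bursts."""
    if recording_duration <= 0:
        raise ValueError("recording_duration must be positive")
    if not events:
        return BurstStats(None, np.nan, np.nan, 0.0)
    durations = np.array([e.duration for e in events])
    aucs = np.array([e.auc_amplitude for e in events])
    counts, _ = np.histogram(durations, bins=DURATION_BIN_EDGES)
    return BurstStats(
        duration_hist=counts / counts.sum(),
        mean_duration=float(durations.mean()),
        mean_auc=float(aucs.mean()),
        density=len(events) / recording_duration,
    )


def average_over_bins(per_bin: list[BurstStats]) -> BurstStats:
    """Unweighted mean of per-frequency-bin statistics (NaN-aware)."""
    if not per_bin:
        raise ValueError("no per-bin statistics to average")
    hists = [s.duration_hist for s in per_bin if s.duration_hist is not None]
    return BurstStats(
        duration_hist=np.mean(hists, axis=0) if hists else None,
        mean_duration=float(np.nanmean([s.mean_duration for s in per_bin])),
        mean_auc=float(np.nanmean([s.mean_auc for s in per_bin])),
        density=float(np.mean([s.density for s in per_bin])),
        n_bins_averaged=len(per_bin),
    )


def analyze_recording(
    samples: np.ndarray,
    sample_rate: float,
    thresholds: np.ndarray | None = None,
    freqs=BETA_BIN_FREQS,
    q: float = 75.0,
) -> tuple[BurstStats, list[BurstEvent]]:
    """Full per-recording burst analysis averaged over the 18 beta bins.

    When *thresholds* is None the recording is its own pool (single-subject
    use); cohort runs should pass :func:`cohort_threshold` output instead.
    """
    env = envelope_bank(samples, sample_rate, freqs)
    if thresholds is None:
        thresholds = np.percentile(env, q, axis=-1)
    duration = env.shape[-1] / BURST_RATE
    per_bin, all_events = [], []
    for i, f in enumerate(np.asarray(freqs, float)):
        events = detect_bursts(env[i], float(thresholds[i]), frequency_bin=f)
        per_bin.append(burst_stats(events, duration))
        all_events.extend(events)
    return average_over_bins(per_bin), all_events
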