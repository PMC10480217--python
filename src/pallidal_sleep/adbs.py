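"""Threshold-based adaptive-DBS controller simulation on time-resolved beta.

Beta power is tracked with 5-s sliding Welch windows stepped by 0.5 s,
percent-power normalized per window, and Gaussian-smoothed (sigma = 5 series
samples = 2.5 s). The stimulation-triggering threshold is the median of the
awake biomarker series. The controller ramps the amplitude toward 3 V at
0.4 V/s while beta exceeds the threshold and back toward 0 V otherwise;
stimulation counts as ON while the amplitude is above 0 V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .containers import ConsensusHypnogram, Hypnogram
from .spectral import NFFT, BandDefinition, _norm_mask

WINDOW_S = 5.0
STEP_S = 0.5
SMOOTH_SIGMA = 5.0  # in biomarker-series samples (= 2.5 s)


@dataclass
class BiomarkerSeries:
    """Time-resolved normalized beta power on a uniform 0.5-s step grid."""

    times: np.ndarray  # window start times, s
    beta: np.ndarray
    window: float = WINDOW_S
    step: float = STEP_S

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.beta = np.asarray(self.beta, float)
        if self.times.shape != self.beta.shape:
            raise ValueError("times and beta must match in length")
        if len(self.times) > 1 and not np.allclose(np.diff(self.times), self.step):
            raise ValueError("biomarker series must be uniformly spaced at the step size")


@dataclass
class ControllerConfig:
    threshold: float
    v_min: float = 0.0
    v_max: float = 3.0
    ramp_rate: float = 0.4  # V/s
    #: "amplitude" (ON while amplitude > v_min) or "biomarker" (ON while beta > threshold)
    on_definition: str = "amplitude"

    def __post_init__(self):
        if self.v_min >= self.v_max:
            raise ValueError("v_min must be below v_max")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be positive")


@dataclass
class StimulationTrace:
    times: np.ndarray
    beta: np.ndarray
    amplitude: np.ndarray
    stim_on: np.ndarray
    threshold: float


def sliding_beta(
    samples: np.ndarray,
    sample_rate: float,
    window: float = WINDOW_S,
    step: float = STEP_S,
    sigma: float = SMOOTH_SIGMA,
    bands: BandDefinition | None = None,
) -> BiomarkerSeries:
    """Normalized beta power in left-aligned sliding windows, then smoothed.

    Windows require full support, so a recording of length T yields
    ``1 + floor((T - window)/step)`` windows. Each window is Welch-transformed
    (512-point segments, 50% overlap), percent-power normalized, and its beta
    band summed; the series is then smoothed with a Gaussian kernel of
    standard deviation *sigma* series samples.
    """
    x = np.asarray(samples, float)
    n = x.size
    win = int(round(window * sample_rate))
    hop = int(round(step * sample_rate))
    if n < win:
        raise ValueError(f"recording shorter than one {window}-s window")
    n_win = 1 + (n - win) // hop
    bands = bands or BandDefinition()
    beta = np.empty(n_win)
    chunk = 2000  # windows per batch, bounds the frame-matrix memory
    for c0 in range(0, n_win, chunk):
        c1 = min(c0 + chunk, n_win)
        idx = np.arange(win)[None, :] + hop * np.arange(c0, c1)[:, None]
        freqs, pxx = sps.welch(
            x[idx], fs=sample_rate, window="hann", nperseg=NFFT, noverlap=NFFT // 2, axis=-1
        )
        keep = (freqs >= 2.0) & (freqs <= 80.0)
        freqs, pxx = freqs[keep], pxx[:, keep]
        total = pxx[:, _norm_mask(freqs, bands)].sum(axis=-1)
        if np.any(total <= 0):
            raise ValueError("zero total power in a sliding window")
        norm = 100.0 * pxx / total[:, None]
        beta[c0:c1] = norm[:, bands.beta.mask(freqs)].sum(axis=-1)
    if sigma > 0:
        beta = ndimage.gaussian_filter1d(beta, sigma)
    times = step * np.arange(n_win)
    return BiomarkerSeries(times=times, beta=beta, window=window, step=step)


def awake_threshold(awake_series: BiomarkerSeries | np.ndarray, q: float = 50.0) -> float:
    """The q-th percentile (default: median) of the awake biomarker values."""
    values = awake_series.beta if isinstance(awake_series, BiomarkerSeries) else np.asarray(awake_series, float)
    if values.size == 0:
        raise ValueError("empty awake biomarker series")
    return float(np.percentile(values, q))


def simulate_controller(series: BiomarkerSeries, cfg: ControllerConfig) -> StimulationTrace:
    """Run the ramp controller over the biomarker series.

    The amplitude starts at ``v_min``; at each 0.5-s step it moves by
    ``ramp_rate * step`` toward ``v_max`` if beta exceeds the threshold and
    toward ``v_min`` otherwise, clipped to the voltage borders. The trace is
    a pure function of (series, cfg).
    """
    dt = series.step
    dv = cfg.ramp_rate * dt
    amp = np.empty_like(series.beta)
    a = cfg.v_min
    amp[0] = a
    for i in range(1, series.beta.size):
        a = a + dv if series.beta[i] > cfg.threshold else a - dv
        a = min(cfg.v_max, max(cfg.v_min, a))
        amp[i] = a
    if cfg.on_definition == "biomarker":
        on = series.beta > cfg.threshold
    else:
        on = amp > cfg.v_min
    return StimulationTrace(
        times=series.times, beta=series.beta, amplitude=amp, stim_on=on, threshold=cfg.threshold
    )


def stim_on_fraction(
    trace: StimulationTrace, ch: ConsensusHypnogram | Hypnogram, stage: str
) -> float:
    """Percent of controller steps that are ON within the stage's epochs.

    ``stage`` may be any AASM label or the pooled ``"NREM"``; returns NaN if
    the stage has no steps within the trace.
    """
    wanted = ("N1", "N2", "N3") if stage == "NREM" else (stage,)
    epoch_idx = np.floor((trace.times - ch.start_time) / ch.epoch_length).astype(int)
    valid = (epoch_idx >= 0) & (epoch_idx < len(ch))
    labels = np.asarray(ch.stages, dtype=object)[epoch_idx[valid]]
    in_stage = np.isin(labels, wanted)
    if not in_stage.any():
        return np.nan
    return 100.0 * float(trace.stim_on[valid][in_stage].mean())


def quarter_values(
    values: np.ndarray, mask: np.ndarray, reducer=np.mean
) -> np.ndarray:
    """Reduce a stage-restricted series into four contiguous quarters.

    *mask* selects the steps belonging to the stage; the masked samples are
    split by cumulative stage time into 0-25 / 25-50 / 50-75 / 75-100%
    quarters and reduced (mean by default) per quarter.
    """
    sel = np.asarray(values)[np.asarray(mask, bool)]
    if sel.size < 4:
        raise ValueError("need at least 4 stage samples to form quarters")
    bounds = (np.arange(5) * sel.size) // 4
    return np.array([reducer(sel[bounds[i] : bounds[i + 1]]) for i in range(4)])


def stage_mask(times: np.ndarray, ch: ConsensusHypnogram | Hypnogram, stage: str) -> np.ndarray:
    """Boolean mask of step times lying in the given (possibly pooled) stage."""
    times = np.asarray(times, float)
    wanted = ("N1", "N2", "N3") if stage == "NREM" else (stage,)
    epoch_idx = np.floor((times - ch.start_time) / ch.epoch_length).astype(int)
    ok = (epoch_idx >= 0) & (epoch_idx < len(ch))
    labels = np.full(times.shape, "", dtype=object)
    labels[ok] = np.asarray(ch.stages, dtype=object)[epoch_idx[ok]]
    return np.isin(labels, wanted)


def quarter_analysis(per_subject_quarters: np.ndarray):
    """Friedman test across the four sleep quarters (subjects as blocks).

    *per_subject_quarters* is an ``(n_subjects, 4)`` matrix; subjects with
    missing (NaN) quarters are excluded.
    """
    from .stats import friedman

    m = np.atleast_2d(np.asarray(per_subject_quarters, float))
    m = m[~np.isnan(m).any(axis=1)]
    if m.shape[0] < 2 or m.shape[1] != 4:
        raise ValueError("need >= 2 complete subjects with 4 quarters each")
    return friedman(m)
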