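"""Preprocessing, Welch spectra, percent-power normalization, band powers,
aperiodic (1/f) adjustment, channel selection and stage-averaged spectra.

Conventions: all spectra live on the 2-80 Hz analysis range of a 512-point
FFT at 500 Hz (grid spacing 500/512 ~ 0.977 Hz); normalization expresses
each bin as percent of the summed power over 2-45 and 55-80 Hz (the 45-55 Hz
mains-notch region is excluded from the normalizer); band power is the sum
of normalized bins whose centers fall in the band interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import SignalRecord
from .staging import EpochedSignal

TARGET_RATE = 500.0
NFFT = 512


@dataclass(frozen=True)
class Band:
    """Frequency band ``[lo, hi]``; either edge may be exclusive."""

    lo: float
    hi: float
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        lo_ok = freqs >= self.lo if self.lo_inclusive else freqs > self.lo
        hi_ok = freqs <= self.hi if self.hi_inclusive else freqs < self.hi
        return lo_ok & hi_ok


@dataclass(frozen=True)
class BandDefinition:
    """Canonical band layout for pallidal LFP analysis.

    The 20 Hz boundary bin belongs to high beta only, so low + high beta
    partition the full beta band without double counting.
    """

    theta: Band = field(default_factory=lambda: Band(4.0, 12.0))
    beta: Band = field(default_factory=lambda: Band(13.0, 30.0))
    low_beta: Band = field(default_factory=lambda: Band(13.0, 20.0, hi_inclusive=False))
    high_beta: Band = field(default_factory=lambda: Band(20.0, 30.0))
    analysis_range: tuple[float, float] = (2.0, 80.0)
    norm_ranges: tuple[tuple[float, float], ...] = ((2.0, 45.0), (55.0, 80.0))

    def __getitem__(self, name: str) -> Band:
        band = getattr(self, name, None)
        if not isinstance(band, Band):
            raise KeyError(f"unknown band {name!r}")
        return band


@dataclass
class SpectralEstimate:
    """Frequency grid + power, with normalization / 1/f-adjustment state."""

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool = False
    aperiodic_adjusted: bool = False
    n_epochs_averaged: int = 1

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.asarray(self.power, float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have matching shapes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def preprocess(record: SignalRecord, mains_freq: float = 50.0) -> SignalRecord:
    """Zero-phase notch filtering of mains + harmonics, then downsample to 500 Hz.

    Band-stop Butterworth filters (order 3, 4 Hz bandwidth) are applied
    forward-backward at every harmonic of *mains_freq* below the input
    Nyquist; the signal is then resampled (polyphase, anti-aliased) to
    exactly 500 Hz.
    """
    fs = record.sample_rate
    if fs < TARGET_RATE:
        raise ValueError(f"sample rate {fs} Hz < required {TARGET_RATE} Hz")
    data = record.data.copy()
    nyq = fs / 2.0
    freq = mains_freq
    while freq + 2.0 < nyq:
        sos = sps.butter(3, [freq - 2.0, freq + 2.0], btype="bandstop", fs=fs, output="sos")
        data = sps.sosfiltfilt(sos, data, axis=-1)
        freq += mains_freq
    if fs != TARGET_RATE:
        ratio = Fraction(int(round(TARGET_RATE * 1000)), int(round(fs * 1000)))
        data = sps.resample_poly(data, ratio.numerator, ratio.denominator, axis=-1)
    return SignalRecord(
        channels=list(record.channels),
        sample_rate=TARGET_RATE,
        data=data,
        units=list(record.units),
    )


def welch_psd(samples: np.ndarray, sample_rate: float = TARGET_RATE) -> SpectralEstimate:
    """One-sided Welch PSD, 512-point Hann segments, 50% overlap, 2-80 Hz.

    The grid spacing is ``sample_rate/512`` (0.9765625 Hz at 500 Hz).
    Segments shorter than 512 samples are dropped by construction; input
    shorter than one segment is an error.
    """
    samples = np.asarray(samples, float)
    if samples.shape[-1] < NFFT:
        raise ValueError(f"need >= {NFFT} samples for one Welch segment")
    freqs, pxx = sps.welch(
        samples, fs=sample_rate, window="hann", nperseg=NFFT, noverlap=NFFT // 2, axis=-1
    )
    keep = (freqs >= 2.0) & (freqs <= 80.0)
    return SpectralEstimate(freqs=freqs[keep], power=pxx[..., keep] if pxx.ndim > 1 else pxx[keep])


def _norm_mask(freqs: np.ndarray, bands: BandDefinition) -> np.ndarray:
    mask = np.zeros_like(freqs, bool)
    for lo, hi in bands.norm_ranges:
        mask |= (freqs >= lo) & (freqs <= hi)
    return mask


def normalize_psd(spec: SpectralEstimate, bands: BandDefinition | None = None) -> SpectralEstimate:
    """Scale the PSD so summed power over 2-45 and 55-80 Hz equals 100.

    Re-normalizing an already-normalized spectrum is rejected rather than
    silently reapplied.
    """
    if spec.normalized:
        raise ValueError("spectrum is already normalized")
    bands = bands or BandDefinition()
    mask = _norm_mask(spec.freqs, bands)
    total = spec.power[..., mask].sum(axis=-1, keepdims=spec.power.ndim > 1)
    if np.any(total <= 0):
        raise ValueError("zero total power in normalization ranges")
    return SpectralEstimate(
        freqs=spec.freqs,
        power=100.0 * spec.power / total,
        normalized=True,
        aperiodic_adjusted=spec.aperiodic_adjusted,
        n_epochs_averaged=spec.n_epochs_averaged,
    )


def band_power(spec: SpectralEstimate, band: Band | str, bands: BandDefinition | None = None) -> float:
    """Sum of normalized power over bins whose centers lie in *band*."""
    if not spec.normalized:
        raise ValueError("band_power expects a normalized spectrum")
    if isinstance(band, str):
        band = (bands or BandDefinition())[band]
    mask = band.mask(spec.freqs)
    if not mask.any():
        raise ValueError(f"band {band.lo}-{band.hi} Hz outside the spectral grid")
    return float(spec.power[mask].sum())


@dataclass
class AperiodicFit:
    """Power-law (knee-free) fit of the 1/f background in log-log space."""

    offset: float
    exponent: float
    fit_range: tuple[float, float]
    freqs: np.ndarray
    residual_periodic: np.ndarray  # log10-power above the aperiodic fit

    def model_log_power(self) -> np.ndarray:
        return self.offset - self.exponent * np.log10(self.freqs)


def fit_aperiodic(
    spec: SpectralEstimate,
    fit_range: tuple[float, float] = (2.0, 45.0),
    mad_k: float = 3.0,
    n_iter: int = 3,
) -> AperiodicFit:
    """Robust power-law fit of log10 power vs log10 frequency.

    Iteratively: least-squares line fit, mask points more than ``mad_k`` MADs
    *above* the line (oscillatory peaks), refit. The residual periodic
    spectrum is log10(power) minus the fitted line over the fit range.
    """
    lo, hi = fit_range
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    f, p = spec.freqs[sel], spec.power[sel]
    if np.any(p <= 0):
        raise ValueError("aperiodic fit requires strictly positive power")
    lf, lp = np.log10(f), np.log10(p)
    use = np.ones_like(lf, bool)
    slope = intercept = 0.0
    for _ in range(n_iter):
        slope, intercept = np.polyfit(lf[use], lp[use], 1)
        resid = lp - (intercept + slope * lf)
        mad = np.median(np.abs(resid[use] - np.median(resid[use])))
        if mad == 0:
            break
        keep = resid <= mad_k * mad
        if keep.sum() < 3 or np.array_equal(keep, use):
            use = keep if keep.sum() >= 3 else use
            break
        use = keep
    resid = lp - (intercept + slope * lf)
    return AperiodicFit(
        offset=float(intercept),
        exponent=float(-slope),
        fit_range=fit_range,
        freqs=f,
        residual_periodic=resid,
    )


def aperiodic_adjusted(spec: SpectralEstimate, **kwargs) -> SpectralEstimate:
    """Periodic residual spectrum (log10 power above the 1/f fit)."""
    fit = fit_aperiodic(spec, **kwargs)
    return SpectralEstimate(
        freqs=fit.freqs,
        power=fit.residual_periodic,
        normalized=spec.normalized,
        aperiodic_adjusted=True,
        n_epochs_averaged=spec.n_epochs_averaged,
    )


def select_channel(awake_beta_by_channel: dict[str, float]) -> str:
    """Channel with the highest awake normalized beta power.

    Exact ties resolve to the lexicographically first channel name.
    """
    if not awake_beta_by_channel:
        raise ValueError("no candidate channels")
    best = max(sorted(awake_beta_by_channel), key=lambda c: awake_beta_by_channel[c])
    return best


def stage_spectra(
    epoched: EpochedSignal,
    stages: tuple[str, ...] = ("W", "NREM", "R"),
    bands: BandDefinition | None = None,
    average: str = "linear",
) -> dict[str, SpectralEstimate]:
    """Per-stage average of per-epoch normalized Welch spectra.

    Each kept 30-s epoch is Welch-transformed and percent-power normalized
    individually, then averaged (arithmetically in linear power by default,
    or in log power with ``average='log'``) within each requested stage.
    Stages with zero kept epochs are omitted.
    """
    bands = bands or BandDefinition()
    out: dict[str, SpectralEstimate] = {}
    for stage in stages:
        epochs = epoched.epochs(stage)
        if not epochs:
            continue
        specs = [normalize_psd(welch_psd(e, epoched.sample_rate), bands) for e in epochs]
        stack = np.stack([s.power for s in specs])
        mean = 10 ** np.log10(stack).mean(axis=0) if average == "log" else stack.mean(axis=0)
        out[stage] = SpectralEstimate(
            freqs=specs[0].freqs,
            power=mean,
            normalized=True,
            n_epochs_averaged=len(specs),
        )
    return out


def stage_band_powers(
    spectra: dict[str, SpectralEstimate], bands: BandDefinition | None = None
) -> dict[str, dict[str, float]]:
    """Theta/beta/low-beta/high-beta band power per stage."""
    bands = bands or BandDefinition()
    return {
        stage: {
            name: band_power(spec, name, bands)
            for name in ("theta", "beta", "low_beta", "high_beta")
        }
        for stage, spec in spectra.items()
    }
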