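"""Synthetic polysomnography + pallidal LFP generator with known ground truth.

Every downstream estimator in this package (sleep metrics, RSWA, spectra,
beta bursts, the adaptive-stimulation controller, cohort statistics) is
exercised against signals produced here, where the generating parameters are
known exactly:

* Hypnograms come from a semi-Markov chain over {W, N1, N2, N3, R} with
  exponential bout dwell times quantized to 30-s epochs, a deterministic
  initial wake run (sleep latency), and explicitly injected long (>2 min)
  wake intrusions whose count is the ground truth for the sleep-fragmentation
  statistic. Brief arousal bouts arising from the chain itself are capped at
  120 s so they never contribute to the fragmentation count.
* LFP is 1/f-shaped background noise plus a stage-gated theta sinusoid and
  Hann-windowed beta-band sinusoid packets ("bursts") whose start, duration
  and carrier frequency are logged. The Hann packet gives an analytically
  known amplitude envelope for oracle tests.
* Chin EMG is 10-70 Hz bandlimited noise with per-stage variance; during REM
  a chosen fraction of 3-s segments is raised above the atonia criterion and
  flagged in the ground truth (the RSWA construct).
* Cohorts bundle per-subject signals, a second scorer (independent per-epoch
  relabelling at a configurable disagreement rate), and clinical covariates
  linked monotonically to the injected beta level.

All randomness flows through one seeded :class:`numpy.random.Generator`
passed down from a single integer seed; identical seeds give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .containers import EPOCH_LENGTH, NREM_STAGES, STAGES, Hypnogram, SignalRecord

# --------------------------------------------------------------------------
# parameter types
# --------------------------------------------------------------------------


def _default_transitions() -> dict[str, dict[str, float]]:
    return {
        "W": {"N1": 1.0},
        "N1": {"N2": 0.70, "W": 0.15, "R": 0.15},
        "N2": {"N3": 0.35, "N1": 0.15, "R": 0.25, "W": 0.25},
        "N3": {"N2": 0.70, "N1": 0.10, "W": 0.20},
        "R": {"N1": 0.40, "N2": 0.40, "W": 0.20},
    }


def _default_dwell() -> dict[str, float]:
    return {"W": 45.0, "N1": 60.0, "N2": 420.0, "N3": 360.0, "R": 360.0}


@dataclass
class HypnogramParams:
    """Semi-Markov hypnogram parameters.

    ``wake_intrusion_rate`` is the expected number of >2-min wake bouts per
    night (Poisson distributed); ``intrusion_dwell`` is the log-normal
    (mu, sigma) of their duration in seconds, floored at 150 s so every
    injected intrusion strictly exceeds the 120-s fragmentation criterion.
    """

    total_time: float = 494.0 * 60
    sleep_onset_delay: float = 3000.0
    mean_dwell: dict[str, float] = field(default_factory=_default_dwell)
    transition_weights: dict[str, dict[str, float]] = field(default_factory=_default_transitions)
    wake_intrusion_rate: float = 14.0
    intrusion_dwell: tuple[float, float] = (np.log(240.0), 0.5)
    #: chain-generated (brief-arousal) wake bouts are truncated at this many epochs
    max_brief_wake_epochs: int = 4

    def validate(self) -> None:
        if self.total_time <= 0 or round(self.total_time) % 30 != 0:
            raise ValueError("total_time must be a positive multiple of 30 s")
        if any(d <= 0 for d in self.mean_dwell.values()):
            raise ValueError("mean dwell times must be positive")
        for src, row in self.transition_weights.items():
            if src not in STAGES:
                raise ValueError(f"unknown stage {src!r} in transition_weights")
            if sum(row.values()) <= 0:
                raise ValueError(f"transition weights from {src!r} not normalizable")
        if self.wake_intrusion_rate < 0:
            raise ValueError("wake_intrusion_rate must be >= 0")


@dataclass
class LfpProfile:
    """Stage-dependent generative parameters for one pallidal LFP channel."""

    aperiodic_offset: float = 0.0
    aperiodic_exponent: float = 1.5
    burst_rate_by_stage: dict[str, float] = field(
        default_factory=lambda: {"W": 0.40, "N1": 0.30, "N2": 0.12, "N3": 0.08, "R": 0.30}
    )
    #: log-normal (mu, sigma) of burst duration (s), per stage
    burst_duration_dist: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {s: (np.log(0.40), 0.40) for s in STAGES}
    )
    burst_center_freq: float = 20.0
    burst_amplitude: float = 0.25
    theta_power_by_stage: dict[str, float] = field(
        default_factory=lambda: {"W": 0.06, "N1": 0.08, "N2": 0.09, "N3": 0.11, "R": 0.10}
    )
    theta_freq: float = 6.0
    sample_rate: float = 500.0

    def validate(self) -> None:
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic exponent must be >= 0")
        if any(r < 0 for r in self.burst_rate_by_stage.values()):
            raise ValueError("burst rates must be >= 0")
        if not 13.0 <= self.burst_center_freq <= 30.0:
            raise ValueError("burst center frequency must lie in 13-30 Hz")
        if self.sample_rate < 200:
            raise ValueError("sample_rate must be >= 200 Hz")


@dataclass
class EmgProfile:
    """Chin-EMG generative parameters (variances in a.u.^2)."""

    variance_by_stage: dict[str, float] = field(
        default_factory=lambda: {"W": 4.0, "N1": 1.2, "N2": 1.0, "N3": 1.0, "R": 0.25}
    )
    rswa_fraction_target: float = 0.0
    #: variance of a flagged REM segment, as a multiple of the mean NREM variance
    rswa_variance_factor: float = 4.0
    twitch_rate: float = 0.0
    sample_rate: float = 500.0

    def validate(self) -> None:
        if any(v <= 0 for v in self.variance_by_stage.values()):
            raise ValueError("stage variances must be positive")
        if not 0.0 <= self.rswa_fraction_target <= 1.0:
            raise ValueError("rswa_fraction_target must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Event log of everything the generator injected."""

    true_hypnogram: Hypnogram | None = None
    #: (start_s, duration_s, center_freq_hz) per injected burst
    true_burst_events: list[tuple[float, float, float]] = field(default_factory=list)
    #: indices into the temporally ordered list of 3-s REM segments
    true_rswa_segments: list[int] = field(default_factory=list)
    #: epoch index and length (epochs) of each injected >2-min wake intrusion
    true_wake_intrusions: list[tuple[int, int]] = field(default_factory=list)
    profile_label: str = ""
    beta_scale: float = 1.0

    def validate_against(self, duration: float) -> None:
        for start, dur, _ in self.true_burst_events:
            if dur <= 0 or start < 0 or start > duration:
                raise ValueError("burst event outside recording bounds")


# --------------------------------------------------------------------------
# hypnogram generation
# --------------------------------------------------------------------------


def _sample_state(rng: np.random.Generator, row: dict[str, float]) -> str:
    names = sorted(row)
    w = np.array([row[n] for n in names], dtype=float)
    return names[rng.choice(len(names), p=w / w.sum())]


def generate_hypnogram(params: HypnogramParams, seed: int) -> tuple[Hypnogram, GroundTruth]:
    """Draw one night's hypnogram; returns the hypnogram and its event log.

    The first epoch is always W; the initial wake run is the (quantized)
    sleep-onset delay. Long wake intrusions are injected afterwards by
    overwriting sleep segments flanked by sleep, so the downstream
    fragmentation count equals the number of logged intrusions.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n_epochs = int(round(params.total_time / EPOCH_LENGTH))

    seq: list[str] = []
    n_onset = max(1, int(round(params.sleep_onset_delay / EPOCH_LENGTH)))
    seq.extend(["W"] * min(n_onset, n_epochs))
    state = "W"
    while len(seq) < n_epochs:
        state = _sample_state(rng, params.transition_weights[state])
        dwell = rng.exponential(params.mean_dwell[state])
        k = max(1, int(round(dwell / EPOCH_LENGTH)))
        if state == "W":
            k = min(k, params.max_brief_wake_epochs)
        seq.extend([state] * k)
    seq = seq[:n_epochs]

    stages = np.array(seq, dtype=object)
    truth = GroundTruth(true_wake_intrusions=[])
    n_intr = rng.poisson(params.wake_intrusion_rate)
    mu, sigma = params.intrusion_dwell
    for _ in range(n_intr):
        dur_s = max(150.0, rng.lognormal(mu, sigma))
        k = int(np.ceil(dur_s / EPOCH_LENGTH))  # >= 5 epochs, strictly > 120 s
        placed = False
        for _try in range(200):
            if n_epochs - k <= 1:
                break
            p = int(rng.integers(1, n_epochs - k))
            lo, hi = p - 1, p + k  # flanking epochs
            if stages[lo] == "W" or stages[hi] == "W":
                continue
            # avoid merging with existing wake runs (would distort the count)
            if np.any(stages[p : p + k] == "W"):
                continue
            placed = True
            stages[p : p + k] = "W"
            truth.true_wake_intrusions.append((p, k))
            break
        if not placed:
            continue
    h = Hypnogram(stages=stages)
    truth.true_hypnogram = h
    return h, truth


# --------------------------------------------------------------------------
# LFP generation
# --------------------------------------------------------------------------


def _one_over_f_noise(
    n: int, fs: float, exponent: float, offset: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with PSD shape f**(-exponent) and total power 10**offset.

    The shaped noise is rescaled to variance ``10**offset``, so *offset* sets
    the background level in log10 power units and *exponent* the 1/f slope
    independently of the recording length.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    if sd > 0:
        x *= 10.0 ** (offset / 2.0) / sd
    return x


def generate_lfp(
    hypnogram: Hypnogram, profile: LfpProfile, seed: int, channel_name: str = "GPi-01"
) -> tuple[SignalRecord, GroundTruth]:
    """Synthesize one bipolar pallidal LFP channel matching *hypnogram*.

    Signal = 1/f background + stage-gated theta sinusoid + Hann-windowed
    sinusoid packets at the beta carrier frequency, at the stage-specific
    Poisson rate. Every packet is logged in the returned ground truth.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    fs = profile.sample_rate
    n = int(round(hypnogram.duration * fs))
    x = _one_over_f_noise(n, fs, profile.aperiodic_exponent, profile.aperiodic_offset, rng)

    spe = int(round(EPOCH_LENGTH * fs))
    t = np.arange(n) / fs
    theta_amp = np.zeros(n)
    for k, stage in enumerate(hypnogram.stages):
        theta_amp[k * spe : (k + 1) * spe] = profile.theta_power_by_stage[str(stage)]
    x += theta_amp * np.sin(2 * np.pi * profile.theta_freq * t + rng.uniform(0, 2 * np.pi))

    truth = GroundTruth(true_hypnogram=hypnogram)
    fc = profile.burst_center_freq
    for k, stage in enumerate(hypnogram.stages):
        rate = profile.burst_rate_by_stage[str(stage)]
        mu, sigma = profile.burst_duration_dist[str(stage)]
        for _ in range(rng.poisson(rate * EPOCH_LENGTH)):
            dur = float(np.clip(rng.lognormal(mu, sigma), 0.1, 5.0))
            start = k * EPOCH_LENGTH + rng.uniform(0, EPOCH_LENGTH)
            i0 = int(round(start * fs))
            m = int(round(dur * fs))
            if i0 + m > n:
                m = n - i0
                if m < int(0.1 * fs):
                    continue
                dur = m / fs
            env = np.hanning(m)
            phase = rng.uniform(0, 2 * np.pi)
            x[i0 : i0 + m] += (
                profile.burst_amplitude * env * np.sin(2 * np.pi * fc * (np.arange(m) / fs) + phase)
            )
            truth.true_burst_events.append((start, dur, fc))
    truth.validate_against(hypnogram.duration)
    record = SignalRecord(channels=[(channel_name, "LFP")], sample_rate=fs, data=x[None, :])
    return record, truth


# --------------------------------------------------------------------------
# EMG generation
# --------------------------------------------------------------------------

SEGMENT_LENGTH = 3.0  # s; IRBDSG-style RSWA segment


def generate_emg(
    hypnogram: Hypnogram, profile: EmgProfile, seed: int
) -> tuple[SignalRecord, GroundTruth]:
    """Synthesize a chin-EMG channel with per-stage variance and RSWA flags.

    Each 30-s epoch holds ten 3-s segments; segment variances are set exactly
    to the stage target. A ``rswa_fraction_target`` fraction of REM segments
    (chosen uniformly) gets variance ``rswa_variance_factor`` times the mean
    NREM variance — comfortably above the "2 x 5th NREM percentile" atonia
    criterion — and is recorded in the ground truth.
    """
    profile.validate()
    stages = hypnogram.stages
    has_rem = np.any(stages == "R")
    has_nrem = np.any(np.isin(stages, NREM_STAGES))
    if has_rem and not has_nrem:
        raise ValueError("hypnogram has REM but no NREM: RSWA reference undefined")

    rng = np.random.default_rng(seed)
    fs = profile.sample_rate
    n = int(round(hypnogram.duration * fs))
    sos = sps.butter(4, [10.0, 70.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))

    segs_per_epoch = int(round(EPOCH_LENGTH / SEGMENT_LENGTH))
    sps_seg = int(round(SEGMENT_LENGTH * fs))
    nrem_var = float(
        np.mean([profile.variance_by_stage[s] for s in NREM_STAGES])
    )

    rem_epochs = np.flatnonzero(stages == "R")
    n_rem_segs = len(rem_epochs) * segs_per_epoch
    n_flag = int(round(profile.rswa_fraction_target * n_rem_segs))
    flagged = set(rng.choice(n_rem_segs, size=n_flag, replace=False)) if n_flag else set()

    truth = GroundTruth(true_hypnogram=hypnogram, true_rswa_segments=sorted(int(i) for i in flagged))
    rem_seg_counter = 0
    for k, stage in enumerate(stages):
        for j in range(segs_per_epoch):
            i0 = k * segs_per_epoch * sps_seg + j * sps_seg
            seg = x[i0 : i0 + sps_seg]
            if seg.size == 0:
                continue
            target = profile.variance_by_stage[str(stage)]
            if stage == "R":
                if rem_seg_counter in flagged:
                    target = profile.rswa_variance_factor * nrem_var
                rem_seg_counter += 1
            sd = seg.std()
            if sd > 0:
                seg *= np.sqrt(target) / sd

    # optional brief REM twitches (short variance transients, not flagged)
    if profile.twitch_rate > 0:
        for k in rem_epochs:
            for _ in range(rng.poisson(profile.twitch_rate * EPOCH_LENGTH / 60.0)):
                i0 = k * segs_per_epoch * sps_seg + int(rng.uniform(0, (EPOCH_LENGTH - 0.3) * fs))
                m = int(0.25 * fs)
                x[i0 : i0 + m] *= 3.0

    record = SignalRecord(channels=[("Chin", "EMG")], sample_rate=fs, data=x[None, :])
    return record, truth


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


def pd_like_hypnogram_params(total_time: float | None = None) -> HypnogramParams:
    """Fragmented, long-latency night (emulating the PD group's architecture)."""
    p = HypnogramParams()
    p.mean_dwell = dict(_default_dwell(), R=300.0)
    if total_time is not None:
        p = replace(p, total_time=total_time, sleep_onset_delay=min(p.sleep_onset_delay, total_time / 4))
    return p


def dystonia_like_hypnogram_params(total_time: float | None = None) -> HypnogramParams:
    """Consolidated, short-latency night (emulating the dystonia group)."""
    p = HypnogramParams(
        total_time=509.0 * 60,
        sleep_onset_delay=840.0,
        wake_intrusion_rate=9.0,
        intrusion_dwell=(np.log(180.0), 0.5),
    )
    p.mean_dwell = dict(_default_dwell(), R=420.0)
    if total_time is not None:
        p = replace(p, total_time=total_time, sleep_onset_delay=min(p.sleep_onset_delay, total_time / 4))
    return p


def pd_like_lfp_profile() -> LfpProfile:
    """Dense, long beta bursts in every stage; moderate theta."""
    return LfpProfile(
        burst_rate_by_stage={"W": 0.40, "N1": 0.30, "N2": 0.12, "N3": 0.08, "R": 0.30},
        burst_duration_dist={s: (np.log(0.45), 0.40) for s in STAGES},
        burst_amplitude=0.30,
        theta_power_by_stage={"W": 0.05, "N1": 0.07, "N2": 0.08, "N3": 0.10, "R": 0.08},
    )


def dystonia_like_lfp_profile() -> LfpProfile:
    """Sparser, shorter beta bursts; elevated theta (the dystonia signature)."""
    return LfpProfile(
        burst_rate_by_stage={"W": 0.15, "N1": 0.10, "N2": 0.05, "N3": 0.04, "R": 0.10},
        burst_duration_dist={s: (np.log(0.30), 0.40) for s in STAGES},
        burst_amplitude=0.18,
        theta_power_by_stage={"W": 0.10, "N1": 0.13, "N2": 0.14, "N3": 0.16, "R": 0.15},
    )


def pd_like_emg_profile() -> EmgProfile:
    return EmgProfile(rswa_fraction_target=0.26)


def dystonia_like_emg_profile() -> EmgProfile:
    return EmgProfile(rswa_fraction_target=0.08)


@dataclass
class SubjectData:
    """One synthetic subject: signals, dual hypnograms, covariates, truth."""

    subject_id: str
    diagnosis: str  # "PD" | "dystonia"
    hypnogram: Hypnogram  # scorer 1 == generator truth
    hypnogram2: Hypnogram  # simulated second scorer
    lfp: SignalRecord
    emg: SignalRecord
    truth: GroundTruth
    clinical: dict[str, float | str]


@dataclass
class CohortBundle:
    subjects: list[SubjectData]
    seed: int

    def group(self, diagnosis: str) -> list[SubjectData]:
        return [s for s in self.subjects if s.diagnosis == diagnosis]


def _relabel(h: Hypnogram, rate: float, rng: np.random.Generator) -> Hypnogram:
    """Independent per-epoch relabelling with probability *rate*."""
    stages = h.stages.copy()
    flip = rng.random(len(stages)) < rate
    for i in np.flatnonzero(flip):
        others = [s for s in STAGES if s != stages[i]]
        stages[i] = others[rng.integers(len(others))]
    return Hypnogram(stages=stages)


def generate_cohort(
    n_pd: int,
    n_dyst: int,
    seed: int,
    total_time: float | None = None,
    disagreement_rate: float = 0.144,
    beta_scale_range: tuple[float, float] = (0.5, 2.0),
    psqi_link_slope: float = 6.0,
    psqi_noise_sd: float = 1.2,
    sample_rate: float = 500.0,
) -> CohortBundle:
    """Generate a two-group cohort with an injected PSQI <-> beta link.

    Each subject gets a per-subject beta scale ``s`` drawn log-uniformly from
    ``beta_scale_range``; burst rate and amplitude both scale with ``s``, and
    (for the PD-like group) PSQI follows ``10 + slope*log2(s) + noise``
    clipped to the 0-21 scale, a monotone link detectable by Spearman
    correlation against measured NREM beta power. Dystonia-like PSQI is
    generated without any link. RBDSQ (PD only) is a noisy monotone function
    of PSQI, and the off-medication motor score tracks ``s`` as well.
    """
    if n_pd < 0 or n_dyst < 0:
        raise ValueError("group sizes must be >= 0")
    rng = np.random.default_rng(seed)
    subjects: list[SubjectData] = []
    specs = [("PD", i + 1) for i in range(n_pd)] + [("dystonia", i + 1) for i in range(n_dyst)]
    for diagnosis, idx in specs:
        sub_seed = int(rng.integers(2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        if diagnosis == "PD":
            hp = pd_like_hypnogram_params(total_time)
            lp, ep = pd_like_lfp_profile(), pd_like_emg_profile()
            label = "PD-like"
        else:
            hp = dystonia_like_hypnogram_params(total_time)
            lp, ep = dystonia_like_lfp_profile(), dystonia_like_emg_profile()
            label = "dystonia-like"
        lo, hi = np.log(beta_scale_range[0]), np.log(beta_scale_range[1])
        s = float(np.exp(sub_rng.uniform(lo, hi)))
        lp = replace(
            lp,
            burst_rate_by_stage={k: v * s for k, v in lp.burst_rate_by_stage.items()},
            burst_amplitude=lp.burst_amplitude * np.sqrt(s),
            sample_rate=sample_rate,
        )
        ep = replace(ep, sample_rate=sample_rate)

        h, h_truth = generate_hypnogram(hp, int(sub_rng.integers(2**31 - 1)))
        lfp, l_truth = generate_lfp(h, lp, int(sub_rng.integers(2**31 - 1)))
        emg, e_truth = generate_emg(h, ep, int(sub_rng.integers(2**31 - 1)))
        h2 = _relabel(h, disagreement_rate, sub_rng)

        truth = GroundTruth(
            true_hypnogram=h,
            true_burst_events=l_truth.true_burst_events,
            true_rswa_segments=e_truth.true_rswa_segments,
            true_wake_intrusions=h_truth.true_wake_intrusions,
            profile_label=label,
            beta_scale=s,
        )
        if diagnosis == "PD":
            psqi = float(np.clip(round(10 + psqi_link_slope * np.log2(s) + sub_rng.normal(0, psqi_noise_sd)), 0, 21))
            rbdsq = float(np.clip(round(0.6 * psqi - 4 + sub_rng.normal(0, 1.5)), 0, 13))
            motor_off = float(np.clip(round(45 + 20 * np.log2(s) + sub_rng.normal(0, 4)), 5, 100))
            motor_on = float(np.clip(round(motor_off * 0.5 + sub_rng.normal(0, 3)), 0, 100))
        else:
            psqi = float(np.clip(round(sub_rng.normal(7, 4)), 0, 21))
            rbdsq = np.nan
            motor_off = float(np.clip(round(sub_rng.normal(16, 8)), 1, 60))
            motor_on = np.nan
        clinical = {
            "subject_id": f"{'PD' if diagnosis == 'PD' else 'Dyst'}-{idx}",
            "diagnosis": diagnosis,
            "nights": 1,
            "psqi": psqi,
            "rbdsq": rbdsq,
            "motor_off": motor_off,
            "motor_on": motor_on,
            "beta_scale": s,
        }
        subjects.append(
            SubjectData(
                subject_id=str(clinical["subject_id"]),
                diagnosis=diagnosis,
                hypnogram=h,
                hypnogram2=h2,
                lfp=lfp,
                emg=emg,
                truth=truth,
                clinical=clinical,
            )
        )
    return CohortBundle(subjects=subjects, seed=seed)
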