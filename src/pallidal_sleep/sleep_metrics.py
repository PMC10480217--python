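"""Hypnogram-derived sleep parameters, fragmentation count, and RSWA.

All durations are reported in minutes, stage proportions as percent of total
sleep time, matching the conventional polysomnography report (TTB, TST,
WASO, SL, RSL, stage percentages, SE, fragmentation count, RSWA%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import (
    EXCLUDED,
    NREM_STAGES,
    ConsensusHypnogram,
    Hypnogram,
    SignalRecord,
)

_MIN = 60.0


@dataclass
class SleepParameters:
    """Classic sleep-architecture summary of one night.

    Durations in minutes; percentages of TST; ``se`` in percent of TTB;
    ``sl``/``rsl`` are NaN when no sleep / no REM occurred. ``sfrag`` and
    ``rswa_pct`` are filled by their dedicated estimators.
    """

    ttb: float
    tst: float
    waso: float
    sl: float
    rsl: float
    pct_n1: float
    pct_n2: float
    pct_n3: float
    pct_rem: float
    se: float
    sfrag: int | None = None
    rswa_pct: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "TTB": self.ttb, "TST": self.tst, "WASO": self.waso,
            "SL": self.sl, "RSL": self.rsl,
            "N1pct": self.pct_n1, "N2pct": self.pct_n2,
            "N3pct": self.pct_n3, "Rpct": self.pct_rem,
            "SE": self.se, "Sfrag": np.nan if self.sfrag is None else self.sfrag,
            "RSWA": self.rswa_pct,
        }


def _stage_array(h: Hypnogram | ConsensusHypnogram) -> np.ndarray:
    return np.asarray(h.stages, dtype=object)


def sleep_parameters(h: Hypnogram | ConsensusHypnogram) -> SleepParameters:
    """Compute TTB, TST, WASO, SL, RSL, stage percentages and SE.

    TTB is the full hypnogram span (EXCLUDED epochs included); sleep/wake
    accounting uses only scored epochs, so EXCLUDED epochs contribute to
    neither TST nor WASO.
    """
    stages = _stage_array(h)
    if len(stages) == 0:
        raise ValueError("empty hypnogram")
    epoch_min = h.epoch_length / _MIN
    ttb = len(stages) * epoch_min

    is_sleep = np.isin(stages, list(NREM_STAGES) + ["R"])
    is_wake = stages == "W"
    tst = float(is_sleep.sum()) * epoch_min

    sleep_idx = np.flatnonzero(is_sleep)
    if sleep_idx.size:
        first_sleep = sleep_idx[0]
        sl = first_sleep * epoch_min
        waso = float(is_wake[first_sleep:].sum()) * epoch_min
    else:
        sl, waso = np.nan, 0.0
    rem_idx = np.flatnonzero(stages == "R")
    rsl = rem_idx[0] * epoch_min if rem_idx.size else np.nan

    def pct(stage: str) -> float:
        return 100.0 * np.sum(stages == stage) * epoch_min / tst if tst > 0 else 0.0

    return SleepParameters(
        ttb=ttb,
        tst=tst,
        waso=waso,
        sl=sl,
        rsl=rsl,
        pct_n1=pct("N1"),
        pct_n2=pct("N2"),
        pct_n3=pct("N3"),
        pct_rem=pct("R"),
        se=100.0 * tst / ttb,
    )


def count_fragmentations(h: Hypnogram | ConsensusHypnogram, min_wake_s: float = 120.0) -> int:
    """Number of sleep interruptions by wakefulness strictly longer than 2 min.

    A fragmentation is a maximal run of W epochs whose total duration exceeds
    *min_wake_s* and that is immediately preceded and followed by sleep
    epochs. Wake before sleep onset (latency) and terminal wake do not count;
    EXCLUDED epochs break runs without counting as sleep or wake.
    """
    stages = _stage_array(h)
    sleep_set = set(NREM_STAGES) | {"R"}
    count, i, n = 0, 0, len(stages)
    while i < n:
        if stages[i] != "W":
            i += 1
            continue
        j = i
        while j < n and stages[j] == "W":
            j += 1
        run_s = (j - i) * h.epoch_length
        before = stages[i - 1] if i > 0 else None
        after = stages[j] if j < n else None
        if run_s > min_wake_s and before in sleep_set and after in sleep_set:
            count += 1
        i = j
    return count


@dataclass
class RswaResult:
    """REM-sleep-without-atonia summary.

    ``rswa_pct`` = 100 * flagged / total 3-s REM segments; the reference is
    the 5th percentile of the NREM chin-EMG segment-variance distribution.
    """

    rswa_pct: float
    n_rem_segments: int
    nrem_variance_p5: float
    flagged_segments: list[int]


def _segment_variances(
    x: np.ndarray, epoch_indices: np.ndarray, fs: float, epoch_length: float, seg_s: float
) -> np.ndarray:
    spe = int(round(epoch_length * fs))
    sps_seg = int(round(seg_s * fs))
    segs_per_epoch = int(round(epoch_length / seg_s))
    out = []
    for k in epoch_indices:
        base = k * spe
        for j in range(segs_per_epoch):
            seg = x[base + j * sps_seg : base + (j + 1) * sps_seg]
            if seg.size == sps_seg:
                out.append(np.var(seg - seg.mean()))
    return np.asarray(out)


def rswa(
    emg: SignalRecord,
    ch: ConsensusHypnogram,
    channel: str | None = None,
    segment_s: float = 3.0,
    nrem_reference: str = "segment",
    criterion_factor: float = 2.0,
    reference_percentile: float = 5.0,
) -> RswaResult:
    """Fraction of 3-s REM segments with chin-EMG variance above atonia limit.

    The EMG is bandpassed 10-70 Hz (zero-phase Butterworth); variance is
    computed on mean-removed non-overlapping *segment_s* windows. A REM
    segment is flagged when its variance exceeds ``criterion_factor`` times
    the ``reference_percentile``-th percentile of the NREM variance
    distribution. ``nrem_reference`` selects whether the NREM distribution is
    built from 3-s segments (default) or whole 30-s epochs.
    """
    if emg.sample_rate < 140:
        raise ValueError("EMG sample rate must be >= 140 Hz for a 10-70 Hz band")
    stages = _stage_array(ch)
    nrem_idx = np.flatnonzero(np.isin(stages, NREM_STAGES))
    rem_idx = np.flatnonzero(stages == "R")
    if nrem_idx.size == 0:
        raise ValueError("no NREM epochs: RSWA reference undefined")

    x = emg.channel(channel) if channel is not None else emg.by_role("EMG").data[0]
    sos = sps.butter(4, [10.0, 70.0], btype="bandpass", fs=emg.sample_rate, output="sos")
    xf = sps.sosfiltfilt(sos, x)

    ref_seg = segment_s if nrem_reference == "segment" else ch.epoch_length
    nrem_vars = _segment_variances(xf, nrem_idx, emg.sample_rate, ch.epoch_length, ref_seg)
    p5 = float(np.percentile(nrem_vars, reference_percentile))
    if p5 <= 0:
        raise ValueError("non-positive NREM reference variance")

    if rem_idx.size == 0:
        return RswaResult(np.nan, 0, p5, [])
    rem_vars = _segment_variances(xf, rem_idx, emg.sample_rate, ch.epoch_length, segment_s)
    flagged = np.flatnonzero(rem_vars > criterion_factor * p5)
    pct = 100.0 * flagged.size / rem_vars.size
    return RswaResult(pct, int(rem_vars.size), p5, [int(i) for i in flagged])


def parameters_with_extras(
    h: Hypnogram | ConsensusHypnogram,
    emg: SignalRecord | None = None,
    ch: ConsensusHypnogram | None = None,
) -> SleepParameters:
    """Full per-night parameter row: architecture + fragmentation + RSWA."""
    params = sleep_parameters(h)
    params.sfrag = count_fragmentations(h)
    if emg is not None and ch is not None:
        stages = _stage_array(ch)
        if np.any(np.isin(stages, NREM_STAGES)) and np.any(stages == "R"):
            params.rswa_pct = rswa(emg, ch).rswa_pct
    return params
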