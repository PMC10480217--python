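"""Dual-scorer consensus, REM-eligibility, and signal epoching.

The consensus rule keeps a 30-s epoch only when both scorers assigned the
same stage; disagreeing epochs are marked EXCLUDED and dropped from every
downstream computation. Recordings whose consensus hypnogram contains fewer
than ``min_rem`` REM epochs are analysed for NREM and wake only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import (
    EXCLUDED,
    NREM_STAGES,
    STAGES,
    ConsensusHypnogram,
    Hypnogram,
    SignalRecord,
    warn_partial_epoch,
)


def consensus(h1: Hypnogram, h2: Hypnogram) -> ConsensusHypnogram:
    """Combine two hypnograms: epoch kept iff both scorers agree.

    ``agreement_fraction`` is kept / total epochs.
    """
    if len(h1) != len(h2):
        raise ValueError(f"hypnogram lengths differ: {len(h1)} vs {len(h2)}")
    agree = h1.stages == h2.stages
    stages = np.where(agree, h1.stages, EXCLUDED)
    frac = float(np.mean(agree)) if len(h1) else 1.0
    return ConsensusHypnogram(stages=stages, agreement_fraction=frac, start_time=h1.start_time)


def rem_eligible(ch: ConsensusHypnogram, min_rem: int = 5) -> bool:
    """True iff the consensus hypnogram holds at least *min_rem* REM epochs.

    Recordings below the cutoff contribute NREM/wake analyses only.
    """
    return ch.count("R") >= min_rem


@dataclass
class EpochedSignal:
    """Stage-keyed 30-s sample slices of one channel.

    ``epochs(stage)`` accepts the five AASM stages plus the pooled ``"NREM"``
    view (N1 ∪ N2 ∪ N3, in temporal order). EXCLUDED epochs are absent.
    """

    samples_by_epoch: dict[int, np.ndarray]
    stage_by_epoch: dict[int, str]
    sample_rate: float

    def epoch_indices(self, stage: str) -> list[int]:
        wanted = NREM_STAGES if stage == "NREM" else (stage,)
        return [i for i in sorted(self.stage_by_epoch) if self.stage_by_epoch[i] in wanted]

    def epochs(self, stage: str) -> list[np.ndarray]:
        return [self.samples_by_epoch[i] for i in self.epoch_indices(stage)]

    def n_epochs(self, stage: str) -> int:
        return len(self.epoch_indices(stage))


def epoch_signal(
    record: SignalRecord, ch: ConsensusHypnogram, channel: str | None = None
) -> EpochedSignal:
    """Slice one channel of *record* into kept 30-s stage epochs.

    Epoch k covers samples ``[k*30*fs, (k+1)*30*fs)`` (half-open, 0-based).
    The record must cover the full hypnogram span; a trailing partial epoch
    of the signal is discarded with a warning.
    """
    if record.duration < ch.duration:
        raise ValueError(
            f"record of {record.duration:.1f} s shorter than hypnogram span {ch.duration:.1f} s"
        )
    warn_partial_epoch(record.duration, ch.duration)
    x = record.channel(channel) if channel is not None else record.data[0]
    spe = int(round(ch.epoch_length * record.sample_rate))
    samples, stages = {}, {}
    for k in ch.kept_indices():
        stage = ch.stages[k]
        samples[int(k)] = x[k * spe : (k + 1) * spe]
        stages[int(k)] = str(stage)
    return EpochedSignal(samples, stages, record.sample_rate)


def hypnogram_as_consensus(h: Hypnogram) -> ConsensusHypnogram:
    """Lift a single-scorer hypnogram to a trivially agreeing consensus."""
    return ConsensusHypnogram(stages=h.stages.copy(), agreement_fraction=1.0, start_time=h.start_time)


def stage_of_time(ch: ConsensusHypnogram | Hypnogram, t: float) -> str | None:
    """Stage label covering time *t* (seconds from epoch 0), or None outside."""
    k = int(np.floor((t - ch.start_time) / ch.epoch_length))
    if 0 <= k < len(ch):
        return str(ch.stages[k])
    return None


__all__ = [
    "STAGES",
    "EXCLUDED",
    "consensus",
    "rem_eligible",
    "epoch_signal",
    "EpochedSignal",
    "hypnogram_as_consensus",
    "stage_of_time",
]
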