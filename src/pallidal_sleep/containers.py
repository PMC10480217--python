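"""Core data containers: hypnograms and multichannel signal records.

Sleep stages follow the AASM 5-class vocabulary (W, N1, N2, N3, R), scored in
fixed 30-s epochs. A :class:`ConsensusHypnogram` additionally carries an
``EXCLUDED`` marker for epochs on which two scorers disagreed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: AASM stage vocabulary.
STAGES = ("W", "N1", "N2", "N3", "R")
#: N1/N2/N3 pooled view.
NREM_STAGES = ("N1", "N2", "N3")
#: Marker for consensus-rejected epochs.
EXCLUDED = "EXCLUDED"
#: Fixed scoring epoch length in seconds.
EPOCH_LENGTH = 30.0

#: Channel roles a SignalRecord understands.
CHANNEL_ROLES = ("EEG", "EOG", "EMG", "LFP")


def _validate_stages(stages, allow_excluded: bool) -> np.ndarray:
    arr = np.asarray(list(stages), dtype=object)
    valid = set(STAGES) | ({EXCLUDED} if allow_excluded else set())
    bad = sorted({s for s in arr if s not in valid})
    if bad:
        raise ValueError(f"unknown sleep stage labels {bad}; expected {sorted(valid)}")
    return arr


@dataclass(frozen=True)
class Hypnogram:
    """Ordered per-30-s-epoch stage labels.

    Parameters
    ----------
    stages
        Sequence of labels from ``{W, N1, N2, N3, R}``.
    start_time
        Offset of epoch 0 from the recording start, in seconds.
    """

    stages: np.ndarray
    start_time: float = 0.0
    epoch_length: float = field(default=EPOCH_LENGTH, init=False)

    def __post_init__(self):
        object.__setattr__(self, "stages", _validate_stages(self.stages, False))

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        """Total span in seconds."""
        return len(self) * self.epoch_length

    def count(self, stage: str) -> int:
        return int(np.sum(self.stages == stage))


@dataclass(frozen=True)
class ConsensusHypnogram:
    """Dual-scorer consensus: agreeing epochs keep their label, others EXCLUDED."""

    stages: np.ndarray
    agreement_fraction: float
    start_time: float = 0.0
    epoch_length: float = field(default=EPOCH_LENGTH, init=False)

    def __post_init__(self):
        object.__setattr__(self, "stages", _validate_stages(self.stages, True))
        if not 0.0 <= self.agreement_fraction <= 1.0:
            raise ValueError("agreement_fraction must lie in [0, 1]")
        n_kept = int(np.sum(self.stages != EXCLUDED))
        if len(self.stages) and n_kept != round(self.agreement_fraction * len(self.stages)):
            raise ValueError("EXCLUDED count inconsistent with agreement_fraction")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self) * self.epoch_length

    def count(self, stage: str) -> int:
        return int(np.sum(self.stages == stage))

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.stages != EXCLUDED)


@dataclass
class SignalRecord:
    """Uniformly sampled multichannel time series with channel roles.

    ``data`` is a ``(n_channels, n_samples)`` float array; ``channels`` is a
    list of ``(name, role)`` pairs with roles in :data:`CHANNEL_ROLES`.
    """

    channels: list[tuple[str, str]]
    sample_rate: float
    data: np.ndarray
    units: list[str] | None = None

    def __post_init__(self):
        if not self.channels:
            raise ValueError("SignalRecord requires at least one channel")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} channels declared"
            )
        for name, role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ValueError(f"channel {name!r}: unknown role {role!r}")
        if self.units is None:
            self.units = ["a.u."] * len(self.channels)
        elif len(self.units) != len(self.channels):
            raise ValueError("units length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.channels]

    def channel(self, name: str) -> np.ndarray:
        """Samples of the named channel (1-D view)."""
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.names}") from None
        return self.data[i]

    def by_role(self, role: str) -> "SignalRecord":
        """Sub-record containing only channels of one role."""
        idx = [i for i, (_, r) in enumerate(self.channels) if r == role]
        if not idx:
            raise KeyError(f"no channels with role {role!r}")
        return SignalRecord(
            channels=[self.channels[i] for i in idx],
            sample_rate=self.sample_rate,
            data=self.data[idx],
            units=[self.units[i] for i in idx],
        )


def warn_partial_epoch(record_duration: float, hypnogram_duration: float) -> None:
    """Log (warn) when a signal tail does not fill a whole 30-s epoch."""
    extra = record_duration - hypnogram_duration
    if extra > 0:
        warnings.warn(
            f"signal extends {extra:.1f} s past the last full 30-s epoch; "
            "trailing partial epoch discarded",
            stacklevel=3,
        )
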