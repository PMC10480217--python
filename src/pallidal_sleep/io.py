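"""File I/O for signals and hypnograms.

Signals use a minimal plain-text container (documented below); hypnograms and
consensus hypnograms are CSV tables. The signal container is a single file:

* line 1: ``#`` followed by a JSON header with keys ``sample_rate``,
  ``channels`` (list of ``[name, role]`` pairs) and ``units``;
* remaining lines: tab-separated sample rows, one row per time point, one
  column per channel, written with 9 significant digits.

The round trip is lossless up to that decimal quantization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EXCLUDED, ConsensusHypnogram, Hypnogram, SignalRecord

_FLOAT_FMT = "%.9g"


def write_signal(record: SignalRecord, path: str | Path) -> Path:
    """Write a :class:`SignalRecord` to the text container at *path*."""
    path = Path(path)
    header = {
        "sample_rate": record.sample_rate,
        "channels": [list(ch) for ch in record.channels],
        "units": record.units,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        np.savetxt(fh, record.data.T, fmt=_FLOAT_FMT, delimiter="\t")
    return path


def read_signal(path: str | Path) -> SignalRecord:
    """Read a signal container written by :func:`write_signal`.

    Raises
    ------
    ValueError
        If the header line is missing or malformed, naming the offending
        field where possible.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing '#'-prefixed JSON header line")
        try:
            header = json.loads(first[1:])
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: header is not valid JSON: {exc}") from exc
        for key in ("sample_rate", "channels"):
            if key not in header:
                raise ValueError(f"{path}: header missing field {key!r}")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    channels = [tuple(ch) for ch in header["channels"]]
    return SignalRecord(
        channels=channels,
        sample_rate=float(header["sample_rate"]),
        data=data.T,
        units=header.get("units"),
    )


def write_hypnogram(h: Hypnogram, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"epoch_index": np.arange(len(h)), "stage": h.stages}).to_csv(
        path, index=False
    )
    return path


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    if "stage" not in df.columns:
        raise ValueError(f"{path}: hypnogram CSV lacks a 'stage' column")
    order = np.argsort(df["epoch_index"].to_numpy()) if "epoch_index" in df else slice(None)
    return Hypnogram(stages=df["stage"].to_numpy()[order])


def write_consensus(ch: ConsensusHypnogram, h2: Hypnogram | None, path: str | Path) -> Path:
    """Consensus CSV: epoch_index, stage, scorer2_stage, kept."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(len(ch)),
            "stage": ch.stages,
            "scorer2_stage": h2.stages if h2 is not None else ch.stages,
            "kept": ch.stages != EXCLUDED,
        }
    )
    df.to_csv(path, index=False)
    return path
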