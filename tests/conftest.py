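import numpy as np
import pytest

from pallidal_sleep import Hypnogram, SignalRecord
from pallidal_sleep import synthetic as syn


def make_hypnogram(labels) -> Hypnogram:
    return Hypnogram(stages=np.array(list(labels), dtype=object))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mixed_hypnogram():
    """Short night with wake, all NREM substages, and enough REM."""
    stages = (
        ["W"] * 4 + ["N1"] * 2 + ["N2"] * 8 + ["N3"] * 4
        + ["R"] * 6 + ["N2"] * 4 + ["R"] * 4 + ["W"] * 2
    )
    return make_hypnogram(stages)


@pytest.fixture
def small_record(rng):
    """2-channel 10-s record at 500 Hz for I/O round trips."""
    data = rng.standard_normal((2, 5000))
    return SignalRecord(
        channels=[("GPi-01", "LFP"), ("Chin", "EMG")], sample_rate=500.0, data=data
    )


@pytest.fixture
def nrem_only_hypnogram():
    return make_hypnogram(["N2"] * 8)


@pytest.fixture
def pd_lfp(nrem_only_hypnogram):
    record, truth = syn.generate_lfp(nrem_only_hypnogram, syn.pd_like_lfp_profile(), seed=42)
    return record, truth
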