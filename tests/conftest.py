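import numpy as np
import pytest

from pwvnet.preprocess import WORKING_FS, EcgRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_record():
    """10 s, 5 Hz unit tone sampled at 360 Hz."""
    fs = 360.0
    t = np.arange(int(10 * fs)) / fs
    return EcgRecord(np.sin(2 * np.pi * 5.0 * t), fs, record_id="tone5")


def make_record(samples, fs=WORKING_FS, labels=None):
    return EcgRecord(np.asarray(samples, dtype=float), fs, labels=labels)
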