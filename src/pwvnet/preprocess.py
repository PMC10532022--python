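"""ECG preprocessing: resampling to the working rate and band-pass denoising.

The pipeline operates at a fixed working rate of 125 Hz.  Denoising uses a
single 8-pole Butterworth band-pass (1--45 Hz) which removes baseline wander
(<1 Hz), power-line interference (50/60 Hz) and most resting EMG activity
(broadband, low energy above 45 Hz).  Filtering is causal single-pass, the
behaviour a real-time defibrillator front end would have; zero-phase
forward-backward filtering would double the effective order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

WORKING_FS = 125.0
"""Working sampling rate (Hz) assumed by segmentation and the TFR stage."""

BAND_LOW_HZ = 1.0
BAND_HIGH_HZ = 45.0
FILTER_ORDER = 8  # total pole count of the band-pass (4th-order prototype)


class RhythmClass(enum.IntEnum):
    """The four rhythm classes, in the fixed serialization order."""

    NORMAL = 0
    OTHER = 1
    VT = 2
    VF = 3


CLASS_ORDER = (RhythmClass.NORMAL, RhythmClass.OTHER, RhythmClass.VT, RhythmClass.VF)
SHOCKABLE = frozenset({RhythmClass.VT, RhythmClass.VF})


@dataclass
class EcgRecord:
    """A sampled single-lead ECG.

    Parameters
    ----------
    samples
        Signal amplitude in mV.
    fs
        Sampling rate in Hz, strictly positive.
    labels
        Optional per-sample rhythm class (`RhythmClass` values), same length
        as ``samples``.
    record_id
        Free-text identifier.
    """

    samples: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != self.samples.shape:
                raise ValueError("labels must have the same length as samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.samples.size / self.fs


def resample(record: EcgRecord, fs_target: float = WORKING_FS) -> EcgRecord:
    """Band-limited resampling of a record to ``fs_target``.

    Uses polyphase resampling (``scipy.signal.resample_poly``) with the exact
    rational rate ratio; the output length is ``round(n * fs_target / fs)``.
    Per-sample labels, when present, are carried over by nearest neighbour.
    """
    if not fs_target > 0:
        raise ValueError(f"target sampling rate must be positive, got {fs_target}")
    if record.fs == fs_target:
        return record

    n_in = len(record)
    n_out = int(round(n_in * fs_target / record.fs))
    ratio = Fraction(fs_target) / Fraction(record.fs)
    ratio = ratio.limit_denominator(10**6)
    y = signal.resample_poly(record.samples, ratio.numerator, ratio.denominator)
    # resample_poly returns ceil(n*up/down) samples; trim/pad to the rounded length
    if y.size > n_out:
        y = y[:n_out]
    elif y.size < n_out:
        y = np.pad(y, (0, n_out - y.size), mode="edge")

    labels = None
    if record.labels is not None:
        src = np.clip(
            np.round(np.arange(n_out) * record.fs / fs_target).astype(np.int64),
            0,
            n_in - 1,
        )
        labels = record.labels[src]
    return EcgRecord(y, fs_target, labels=labels, record_id=record.record_id)


def _bandpass_sos(fs: float = WORKING_FS,
                  low_hz: float = BAND_LOW_HZ,
                  high_hz: float = BAND_HIGH_HZ,
                  order: int = FILTER_ORDER) -> np.ndarray:
    """Second-order sections of the denoising band-pass.

    ``order`` counts poles of the band-pass itself, so the Butterworth
    low-pass prototype has ``order // 2`` poles.
    """
    if order % 2:
        raise ValueError("band-pass pole count must be even")
    return signal.butter(order // 2, [low_hz, high_hz], btype="bandpass",
                         fs=fs, output="sos")


def bandpass(record: EcgRecord) -> EcgRecord:
    """Causal 8-pole Butterworth band-pass (1--45 Hz) at the working rate.

    The record must already be at 125 Hz (call :func:`resample` first); this
    is enforced rather than silently resampled so that the filter's fixed
    design frequencies always mean what they say.
    """
    if abs(record.fs - WORKING_FS) > 1e-9:
        raise ValueError(
            f"bandpass requires fs = {WORKING_FS} Hz, got {record.fs}; resample first"
        )
    sos = _bandpass_sos(record.fs)
    y = signal.sosfilt(sos, record.samples)
    return EcgRecord(y, record.fs, labels=record.labels, record_id=record.record_id)


def preprocess(record: EcgRecord, fs_target: float = WORKING_FS) -> EcgRecord:
    """Resample to the working rate and band-pass filter."""
    return bandpass(resample(record, fs_target))
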