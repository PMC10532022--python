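"""Window Reference Marks (WRMs) and 1.2 s / 150-sample window extraction.

A WRM marks the onset of an analysis window.  Consecutive marks are
constrained to lie between 0.5 s and 1.2 s apart (the RR-interval range of a
50--120 bpm heart rate); each mark opens a 1.2 s window, which at the 125 Hz
working rate is exactly 150 samples.

The mark detector is an energy-peak detector: the rectified signal is
smoothed with a 120 ms moving average, local maxima above an adaptive
threshold (0.3 x the rolling 2 s maximum) become candidates, a 0.5 s
refractory keeps the larger of conflicting candidates, and gaps longer than
1.2 s are filled with the largest remaining local maximum inside the gap
when one exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import WORKING_FS, EcgRecord

WINDOW_SECONDS = 1.2
WINDOW_SAMPLES = 150  # 1.2 s x 125 Hz
WRM_MIN_SECONDS = 0.5
WRM_MAX_SECONDS = 1.2

SMOOTH_SECONDS = 0.120
THRESHOLD_FRACTION = 0.3
ROLLING_MAX_SECONDS = 2.0


@dataclass
class WindowReferenceMarks:
    """Strictly increasing mark indices with gaps of at least 0.5 s."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size > 1:
            gaps = np.diff(self.indices)
            min_gap = int(np.ceil(WRM_MIN_SECONDS * self.fs))
            if np.any(gaps < min_gap):
                raise ValueError(
                    f"mark gaps must be >= {min_gap} samples, got min {gaps.min()}"
                )

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class WindowSet:
    """Fixed-length windows with their mark origins and optional labels."""

    windows: np.ndarray  # (n, 150)
    origins: np.ndarray  # (n,)
    labels: np.ndarray | None
    fs: float = WORKING_FS

    def __post_init__(self) -> None:
        self.windows = np.atleast_2d(np.asarray(self.windows, dtype=np.float64))
        if self.windows.size and self.windows.shape[1] != WINDOW_SAMPLES:
            raise ValueError(
                f"windows must have {WINDOW_SAMPLES} samples, got {self.windows.shape[1]}"
            )
        self.origins = np.asarray(self.origins, dtype=np.int64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)

    def __len__(self) -> int:
        return self.windows.shape[0] if self.windows.size else 0


def detection_function(x: np.ndarray, fs: float) -> np.ndarray:
    """Rectified signal smoothed by a centered 120 ms moving average."""
    width = max(1, int(round(SMOOTH_SECONDS * fs)))
    if width % 2 == 0:
        width += 1
    kernel = np.full(width, 1.0 / width)
    return np.convolve(np.abs(x), kernel, mode="same")


def _rolling_max(d: np.ndarray, width: int) -> np.ndarray:
    """Centered rolling maximum (window clipped at the edges)."""
    from scipy.ndimage import maximum_filter1d

    return maximum_filter1d(d, size=width, mode="nearest")


def detect_wrm(record: EcgRecord) -> WindowReferenceMarks:
    """Detect Window Reference Marks on a filtered 125 Hz record.

    Returns an empty mark list (with a warning) for records shorter than one
    window.  The result is deterministic in the input.
    """
    if abs(record.fs - WORKING_FS) > 1e-9:
        raise ValueError(f"detect_wrm requires fs = {WORKING_FS} Hz, got {record.fs}")
    fs = record.fs
    n = len(record)
    if n < WINDOW_SAMPLES:
        warnings.warn(
            f"record shorter than {WINDOW_SECONDS} s; no marks detected", stacklevel=2
        )
        return WindowReferenceMarks(np.empty(0, dtype=np.int64), fs)

    d = detection_function(record.samples, fs)
    if not np.any(d > 0):
        return WindowReferenceMarks(np.empty(0, dtype=np.int64), fs)

    peaks, _ = sps.find_peaks(d)
    thresh = THRESHOLD_FRACTION * _rolling_max(d, int(round(ROLLING_MAX_SECONDS * fs)))
    candidates = peaks[d[peaks] > thresh[peaks]]
    if candidates.size == 0:
        # flat-topped or monotone signals: fall back to the global maximum
        candidates = np.array([int(np.argmax(d))], dtype=np.int64)

    refractory = int(np.ceil(WRM_MIN_SECONDS * fs))  # 63 samples at 125 Hz
    # greedy by amplitude: the larger of two conflicting candidates survives
    order = candidates[np.argsort(d[candidates], kind="stable")[::-1]]
    accepted: list[int] = []
    for idx in order:
        if all(abs(idx - a) >= refractory for a in accepted):
            accepted.append(int(idx))
    marks = sorted(accepted)

    # fill gaps > 1.2 s with the largest interior local maximum, if insertable
    max_gap = int(round(WRM_MAX_SECONDS * fs))
    all_peaks = set(peaks.tolist())
    changed = True
    while changed:
        changed = False
        out: list[int] = []
        for a, b in zip(marks[:-1], marks[1:]):
            out.append(a)
            if b - a > max_gap:
                inside = [
                    p for p in range(a + refractory, b - refractory + 1)
                    if p in all_peaks and d[p] > 0
                ]
                if inside:
                    best = max(inside, key=lambda p: d[p])
                    out.append(best)
                    changed = True
        out.append(marks[-1])
        marks = out
    return WindowReferenceMarks(np.array(marks, dtype=np.int64), fs)


def extract_windows(record: EcgRecord, marks: WindowReferenceMarks) -> WindowSet:
    """Cut one 150-sample window per mark whose span fits inside the record.

    Marks closer than 1.2 s to the record end are dropped silently (the count
    is available as ``len(marks) - len(result)``).  When the record carries
    per-sample labels, each window is labeled with the class active at its
    mark sample.
    """
    if abs(record.fs - WORKING_FS) > 1e-9:
        raise ValueError(f"extract_windows requires fs = {WORKING_FS} Hz")
    n = len(record)
    keep = marks.indices[marks.indices + WINDOW_SAMPLES <= n]
    windows = np.stack(
        [record.samples[i:i + WINDOW_SAMPLES] for i in keep]
    ) if keep.size else np.empty((0, WINDOW_SAMPLES))
    labels = record.labels[keep] if record.labels is not None and keep.size else (
        np.empty(0, dtype=np.int64) if record.labels is not None else None
    )
    return WindowSet(windows, keep, labels, fs=record.fs)


def segment(record: EcgRecord) -> WindowSet:
    """Detect marks and extract windows in one step."""
    return extract_windows(record, detect_wrm(record))
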