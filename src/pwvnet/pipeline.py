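"""End-to-end composition: records -> windows -> TFR images -> classifier.

Three pipeline variants mirror the ablation of the time-frequency front
end: ``TFR_CNN1`` (no analytic signal, dense classifier), ``Ht_TFR_CNN1``
(analytic signal + dense classifier) and ``Ht_TFR_CNN2`` (analytic signal +
convolutional classifier, the reference configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import evaluate as ev
from .models import build_model, get_spec
from .preprocess import EcgRecord, preprocess
from .segment import WINDOW_SAMPLES, detect_wrm, extract_windows
from .tfr import SmoothingKernel, to_cnn_input, window_to_image

VARIANTS = {
    "TFR_CNN1": {"use_hilbert": False, "model": "CNN1"},
    "Ht_TFR_CNN1": {"use_hilbert": True, "model": "CNN1"},
    "Ht_TFR_CNN2": {"use_hilbert": True, "model": "CNN2"},
}


def records_to_windows(records: list[EcgRecord]):
    """Preprocess and segment a record list; windows concatenated.

    Returns ``(windows (n,150), labels (n,), n_dropped)`` where dropped
    counts marks whose window did not fit inside a record.
    """
    wins, labels = [], []
    n_dropped = 0
    for record in records:
        filtered = preprocess(record)
        marks = detect_wrm(filtered)
        ws = extract_windows(filtered, marks)
        n_dropped += len(marks) - len(ws)
        if len(ws):
            wins.append(ws.windows)
            if ws.labels is not None:
                labels.append(ws.labels)
    windows = np.concatenate(wins) if wins else np.empty((0, WINDOW_SAMPLES))
    y = np.concatenate(labels) if labels else None
    return windows, y, n_dropped


def windows_to_cnn_inputs(windows: np.ndarray, use_hilbert: bool = True,
                          kernel: SmoothingKernel | None = None) -> np.ndarray:
    """TFRI + resize for a window batch; returns (n, 180, 180) float32."""
    out = np.empty((windows.shape[0], 180, 180), dtype=np.float32)
    for i, w in enumerate(windows):
        img = window_to_image(w, use_hilbert=use_hilbert, h=kernel)
        out[i] = to_cnn_input(img)
    return out


@dataclass
class ExperimentResult:
    report: ev.EvalReport
    n_windows: int
    n_dropped: int
    per_class_counts: dict


def run_experiment(records: list[EcgRecord], variant: str = "Ht_TFR_CNN2",
                   epochs: int = 100, repeats: int = ev.DEFAULT_REPEATS,
                   lr: float = ev.DEFAULT_LR, batch: int = ev.DEFAULT_BATCH,
                   seed: int = 0, kernel: SmoothingKernel | None = None,
                   ) -> ExperimentResult:
    """Full repeated-holdout evaluation of one pipeline variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {sorted(VARIANTS)}")
    cfg = VARIANTS[variant]
    windows, y, n_dropped = records_to_windows(records)
    if y is None:
        raise ValueError("records must carry labels for an experiment")
    x = windows_to_cnn_inputs(windows, use_hilbert=cfg["use_hilbert"], kernel=kernel)

    splits = ev.repeated_holdout(y, repeats=repeats, seed=seed)
    confusions, histories = [], []
    for r, (train_idx, test_idx) in enumerate(splits):
        model = build_model(get_spec(cfg["model"]), seed=seed + r)
        hist = ev.train(model, x[train_idx], y[train_idx], epochs=epochs,
                        lr=lr, batch=batch, seed=seed + 1000 + r)
        pred = model.predict(x[test_idx])
        confusions.append(ev.confusion(y[test_idx], pred))
        histories.append(hist)
    counts = {int(c): int(np.sum(y == c)) for c in np.unique(y)}
    return ExperimentResult(ev.EvalReport(confusions, histories),
                            n_windows=len(y), n_dropped=n_dropped,
                            per_class_counts=counts)
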