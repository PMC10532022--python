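"""Synthetic labeled ECG generator for the four rhythm classes.

The generator produces parametric template waveforms, not a differential-
equation heart model; it exists so that every pipeline stage and the
end-to-end classifier can be exercised without downloading clinical data,
and real WFDB records can be substituted wherever an `EcgRecord` is
accepted.

Classes:

* Normal -- a P-QRS-T template train at 50-120 bpm with +/-5% RR jitter;
  the QRS is a Gaussian-derivative burst (localized in time, broadband).
* VT -- fast wide-complex quasi-sinusoid at 150-250 bpm with small
  per-cycle frequency jitter and slow amplitude modulation.
* VF -- irregular oscillation whose frequency performs a per-cycle random
  walk inside 4-7 Hz, with per-cycle amplitude modulation.
* Other -- either an atrial-arrhythmia-like irregular narrow-complex train
  (no P/T waves, fibrillatory ripple) or structured motion-artifact noise.

All records carry additive baseline wander (<1 Hz), 50 Hz power-line
interference and broadband EMG-like noise, at configurable amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EcgRecord, RhythmClass

NORMAL_BPM_RANGE = (50.0, 120.0)
VT_BPM_RANGE = (150.0, 250.0)
VF_HZ_RANGE = (4.0, 7.0)

DEFAULT_FS = 250.0       # deliberately above the 125 Hz working rate
DEFAULT_DURATION = 2.0   # seconds; an AED-style short analysis snippet


@dataclass
class SynthParams:
    """Generation parameters for one record.

    ``rate`` is bpm for Normal/VT and the base oscillation frequency in Hz
    for VF; when None it is drawn uniformly from the class range.  Noise
    amplitudes are in mV against a ~1 mV QRS.
    """

    rhythm_class: RhythmClass
    duration: float = DEFAULT_DURATION
    fs: float = DEFAULT_FS
    seed: int = 0
    rate: float | None = None
    other_kind: str | None = None       # "afib" | "artifact" | None (random)
    noise_baseline: float = 0.12
    noise_powerline: float = 0.05
    noise_emg: float = 0.02

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.rhythm_class = RhythmClass(self.rhythm_class)
        if self.rate is not None:
            ranges = {RhythmClass.NORMAL: NORMAL_BPM_RANGE,
                      RhythmClass.VT: VT_BPM_RANGE,
                      RhythmClass.VF: VF_HZ_RANGE}
            rng = ranges.get(self.rhythm_class)
            if rng and not (rng[0] <= self.rate <= rng[1]):
                raise ValueError(
                    f"rate {self.rate} outside {self.rhythm_class.name} range {rng}")


def _gaussian(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _qrs(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    """Gaussian-derivative (biphasic) QRS burst, peak amplitude ``amp``."""
    z = (t - center) / sigma
    return -amp * z * np.exp(0.5 * (1.0 - z * z))  # scaled so max |.| = amp


def _beat_train(t: np.ndarray, beats: np.ndarray, qrs_sigma: float,
                qrs_amp: float, p_amp: float = 0.0, t_amp: float = 0.0,
                ) -> np.ndarray:
    x = np.zeros_like(t)
    for tb in beats:
        x += _qrs(t, tb, qrs_sigma, qrs_amp)
        if p_amp:
            x += p_amp * _gaussian(t, tb - 0.16, 0.025)
        if t_amp:
            x += t_amp * _gaussian(t, tb + 0.25, 0.050)
    return x


def _normal(t: np.ndarray, rng: np.random.Generator, bpm: float):
    rr = 60.0 / bpm
    beats = []
    tb = rng.uniform(0.15, 0.35)
    while tb < t[-1] + rr:
        beats.append(tb)
        tb += rr * (1.0 + rng.uniform(-0.05, 0.05))
    beats = np.asarray(beats)
    return _beat_train(t, beats, 0.018, 1.0, p_amp=0.15, t_amp=0.30), beats


def _vt(t: np.ndarray, rng: np.random.Generator, bpm: float):
    f0 = bpm / 60.0
    # per-sample frequency with small slow jitter, integrated to a phase
    f = f0 * (1.0 + 0.02 * np.sin(2 * np.pi * rng.uniform(0.2, 0.6) * t
                                  + rng.uniform(0, 2 * np.pi)))
    phase = 2 * np.pi * np.concatenate([[0], np.cumsum(f[:-1])]) * (t[1] - t[0])
    phase += rng.uniform(0, 2 * np.pi)
    amp = 1.0 + 0.1 * np.sin(2 * np.pi * rng.uniform(0.3, 0.8) * t)
    x = amp * (np.sin(phase) + 0.35 * np.sin(2 * phase + 0.8))
    peaks = _phase_events(phase, t)
    return x, peaks


def _vf(t: np.ndarray, rng: np.random.Generator, base_hz: float):
    lo, hi = VF_HZ_RANGE
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    f_inst = np.empty_like(t)
    amp = np.empty_like(t)
    i, f_cur = 0, base_hz
    cycle_starts = []
    while i < len(t):
        cyc = max(2, int(round(1.0 / (f_cur * dt))))
        j = min(len(t), i + cyc)
        f_inst[i:j] = f_cur
        amp[i:j] = rng.uniform(0.5, 1.2)
        cycle_starts.append(t[i])
        f_cur = float(np.clip(f_cur + rng.normal(0.0, 0.5), lo, hi))
        i = j
    # smooth the per-cycle amplitude steps a little
    k = max(1, int(round(0.05 / dt)))
    amp = np.convolve(amp, np.full(k, 1.0 / k), mode="same")
    phase = 2 * np.pi * np.concatenate([[0], np.cumsum(f_inst[:-1])]) * dt
    phase += rng.uniform(0, 2 * np.pi)
    return amp * np.sin(phase), np.asarray(cycle_starts)


def _other(t: np.ndarray, rng: np.random.Generator, kind: str | None):
    if kind is None:
        kind = "afib" if rng.random() < 0.5 else "artifact"
    if kind == "afib":
        beats = []
        tb = rng.uniform(0.1, 0.3)
        while tb < t[-1] + 0.75:
            beats.append(tb)
            tb += rng.uniform(0.35, 0.75)
        beats = np.asarray(beats)
        x = _beat_train(t, beats, 0.012, 0.9)
        f_f = rng.uniform(5.0, 8.0)
        x += 0.12 * np.sin(2 * np.pi * f_f * t + rng.uniform(0, 2 * np.pi))
        return x, beats
    # structured artifact: low-pass filtered telegraph swings + noise bursts
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    steps = rng.choice([-1.0, 1.0], size=len(t)) * rng.uniform(0.5, 1.5)
    hold = max(1, int(round(rng.uniform(0.15, 0.4) / dt)))
    tele = np.repeat(steps[::hold], hold)[:len(t)]
    k = max(1, int(round(0.08 / dt)))
    x = np.convolve(tele, np.full(k, 1.0 / k), mode="same")
    burst = rng.normal(0.0, 0.4, size=len(t)) * (rng.random(len(t)) < 0.3)
    x += np.convolve(burst, np.full(3, 1 / 3), mode="same")
    return x, np.empty(0)


def _phase_events(phase: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Times where the phase crosses pi/2 modulo 2*pi (waveform peaks)."""
    cycles = (phase - np.pi / 2) / (2 * np.pi)
    crossings = np.flatnonzero(np.diff(np.floor(cycles)) > 0)
    return t[crossings]


def generate_record(p: SynthParams) -> tuple[EcgRecord, np.ndarray]:
    """Generate one labeled record plus its ground-truth event times (s).

    Events are QRS centers (Normal, atrial-like Other), waveform peaks (VT)
    or cycle starts (VF); the artifact variant of Other has no events.
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs))
    t = np.arange(n) / p.fs

    cls = p.rhythm_class
    if cls == RhythmClass.NORMAL:
        rate = p.rate if p.rate is not None else rng.uniform(*NORMAL_BPM_RANGE)
        x, events = _normal(t, rng, rate)
    elif cls == RhythmClass.VT:
        rate = p.rate if p.rate is not None else rng.uniform(*VT_BPM_RANGE)
        x, events = _vt(t, rng, rate)
    elif cls == RhythmClass.VF:
        rate = p.rate if p.rate is not None else rng.uniform(*VF_HZ_RANGE)
        x, events = _vf(t, rng, rate)
    elif cls == RhythmClass.OTHER:
        x, events = _other(t, rng, p.other_kind)
    else:  # pragma: no cover -- RhythmClass() already rejects others
        raise ValueError(f"invalid rhythm class {p.rhythm_class!r}")

    x = x + (p.noise_baseline * np.sin(2 * np.pi * rng.uniform(0.15, 0.45) * t
                                       + rng.uniform(0, 2 * np.pi))
             + p.noise_powerline * np.sin(2 * np.pi * 50.0 * t
                                          + rng.uniform(0, 2 * np.pi))
             + p.noise_emg * rng.normal(0.0, 1.0, size=n))
    labels = np.full(n, int(cls), dtype=np.int64)
    record = EcgRecord(x, p.fs, labels=labels,
                       record_id=f"synth-{cls.name.lower()}-{p.seed}")
    return record, events


def generate_dataset(n_per_class: int, fs: float = DEFAULT_FS, seed: int = 0,
                     duration: float = DEFAULT_DURATION,
                     ) -> tuple[list[EcgRecord], list[dict]]:
    """Balanced labeled records for all four classes, with a manifest.

    The manifest lists, per record, the class, per-record seed and drawn
    rate, sufficient to regenerate any record individually.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[EcgRecord] = []
    manifest: list[dict] = []
    for cls in (RhythmClass.NORMAL, RhythmClass.OTHER,
                RhythmClass.VT, RhythmClass.VF):
        for i in range(n_per_class):
            rec_seed = int(rng.integers(0, 2**31 - 1))
            p = SynthParams(cls, duration=duration, fs=fs, seed=rec_seed)
            record, events = generate_record(p)
            record.record_id = f"{cls.name.lower()}-{i:04d}"
            records.append(record)
            manifest.append({
                "record_id": record.record_id,
                "class": cls.name,
                "seed": rec_seed,
                "fs": fs,
                "duration": duration,
                "n_events": int(len(events)),
            })
    return records, manifest
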