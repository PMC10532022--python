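"""Independent reference computations used by the tests.

These deliberately avoid the package's own code paths: the band-pass oracle
is the closed-form magnitude of a bilinear-designed digital Butterworth
band-pass, and the time-frequency oracle is a literal triple-loop evaluation
of the lag-sum definition.
"""

import numpy as np


def butterworth_bandpass_gain(f_hz: float, fs: float = 125.0,
                              f_low: float = 1.0, f_high: float = 45.0,
                              n_poles: int = 8) -> float:
    """|H| of an n-pole digital Butterworth band-pass at frequency f.

    Closed form for the bilinear transform with prewarped edge frequencies:
    with W = tan(pi f / fs), the magnitude is the analog prototype response
    evaluated at (W^2 - W1 W2) / ((W2 - W1) W).
    """
    n = n_poles // 2
    w = np.tan(np.pi * f_hz / fs)
    w1, w2 = np.tan(np.pi * f_low / fs), np.tan(np.pi * f_high / fs)
    u = (w * w - w1 * w2) / ((w2 - w1) * w)
    return float(1.0 / np.sqrt(1.0 + u ** (2 * n)))


def measured_sine_gain(filtered: np.ndarray, f_hz: float, fs: float,
                       settle_s: float = 30.0) -> float:
    """Steady-state amplitude of a unit sine after discarding the transient."""
    n0 = int(settle_s * fs)
    seg = filtered[n0:]
    t = np.arange(n0, n0 + seg.size) / fs
    a = 2.0 * np.mean(seg * np.sin(2 * np.pi * f_hz * t))
    b = 2.0 * np.mean(seg * np.cos(2 * np.pi * f_hz * t))
    return float(np.hypot(a, b))


def wigner_ville_direct(s: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the pseudo Wigner-Ville definition."""
    s = np.asarray(s, dtype=complex)
    n = s.size
    half = (h.size - 1) // 2
    out = np.zeros((n, n))
    for t in range(n):
        for k in range(n):
            acc = 0.0 + 0.0j
            for m in range(-half, half + 1):
                a = s[t + m] if 0 <= t + m < n else 0.0
                b = s[t - m] if 0 <= t - m < n else 0.0
                acc += h[half + m] * a * np.conj(b) * np.exp(-2j * np.pi * k * m / n)
            out[k, t] = 2.0 * acc.real
    return out
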