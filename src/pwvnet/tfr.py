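"""Time-frequency representation of ECG windows.

Each 150-sample window is mapped to a Pseudo Wigner-Ville (PWV) distribution

    PWV[n, k] = 2 * Re sum_m  h[m] s[n+m] conj(s[n-m]) exp(-j 2 pi k m / N)

with lag m in [-(L-1)/2, (L-1)/2], N the window length, samples outside the
window treated as zero.  Because the instantaneous autocorrelation uses lag
pairs (n+m, n-m), frequency row k corresponds to k*fs/(2N) Hz -- twice the
usual DFT grid density.

The Wigner-Ville distribution of a real signal carries mirror artifacts from
negative-frequency content; replacing the signal with its analytic version
(x + j*Hilbert(x)) suppresses them.  Cross-terms between genuine components
are attenuated by the lag-smoothing kernel h (default: Hamming, length 37).

The 150x150 PWV matrix is then reduced to a 45x150 image (TFRI): the 1-45 Hz
band is interpolated onto a 1 Hz row grid, negative values are clipped, and
the image is min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import WORKING_FS
from .segment import WINDOW_SAMPLES

IMAGE_ROWS = 45        # 1 row per Hz, 1..45 Hz
IMAGE_COLS = WINDOW_SAMPLES
CNN_INPUT_SIDE = 180
DEFAULT_KERNEL_LENGTH = 37  # ~N/4, odd


@dataclass(frozen=True)
class SmoothingKernel:
    """Symmetric odd-length lag window, peak-normalized to 1."""

    h: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=np.float64)
        object.__setattr__(self, "h", h)
        if h.ndim != 1 or h.size % 2 == 0:
            raise ValueError("kernel must be a 1-D vector of odd length")
        if not np.allclose(h, h[::-1]):
            raise ValueError("kernel must be symmetric")
        if not np.isclose(h.max(), 1.0):
            raise ValueError("kernel must be peak-normalized (max = 1)")

    def __len__(self) -> int:
        return self.h.size

    @property
    def half(self) -> int:
        return (self.h.size - 1) // 2


def hamming_kernel(length: int = DEFAULT_KERNEL_LENGTH) -> SmoothingKernel:
    """Hamming lag window; the default cross-term smoother."""
    h = np.hamming(length)
    return SmoothingKernel(h / h.max())


def rectangular_kernel(length: int) -> SmoothingKernel:
    """All-ones kernel; spanning all lags it yields the unsmoothed WV."""
    return SmoothingKernel(np.ones(length))


@dataclass
class TfrMatrix:
    """N x N real PWV matrix; row k maps to frequency k*fs/(2N) Hz."""

    values: np.ndarray
    fs: float = WORKING_FS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("TfrMatrix must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TfrMatrix entries must be finite")

    @property
    def freq_axis(self) -> np.ndarray:
        n = self.values.shape[0]
        return np.arange(n) * self.fs / (2 * n)


@dataclass
class TfrImage:
    """45 x 150 normalized intensity image covering the 1-45 Hz band."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (IMAGE_ROWS, IMAGE_COLS):
            raise ValueError(
                f"TfrImage must be {IMAGE_ROWS}x{IMAGE_COLS}, got {self.pixels.shape}"
            )
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("TfrImage pixels must lie in [0, 1]")


def analytic_signal(x: np.ndarray) -> np.ndarray:
    """Analytic signal x + j*H[x] via the FFT Hilbert transformer.

    The real part equals the input exactly; the discrete spectrum has
    (near-)zero energy on the negative-frequency bins.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("analytic_signal requires a 1-D input of length >= 2")
    return x + 1j * np.imag(sps.hilbert(x))


def pwv(s: np.ndarray, h: SmoothingKernel | None = None,
        fs: float = WORKING_FS) -> TfrMatrix:
    """Pseudo Wigner-Ville distribution of a (complex) window.

    Computed with one FFT per time instant over the kernel-weighted
    instantaneous autocorrelation r[n, m] = h[m] s[n+m] conj(s[n-m]); the
    negative lags are placed in the upper FFT bins so that the transform
    matches the direct summation of the definition exactly.
    """
    s = np.asarray(s, dtype=np.complex128)
    if s.ndim != 1:
        raise ValueError("pwv expects a 1-D window")
    n = s.size
    if n < 2:
        raise ValueError("pwv requires a window of length >= 2")
    if h is None:
        h = hamming_kernel()
    if len(h) > n:
        raise ValueError(f"kernel length {len(h)} exceeds window length {n}")

    half = h.half
    padded = np.concatenate([np.zeros(half, complex), s, np.zeros(half, complex)])
    # r[m_idx, t]: rows are lags 0..half then (wrapped) -half..-1
    acf = np.zeros((n, n), dtype=np.complex128)
    idx = np.arange(n) + half  # positions of s[t] inside `padded`
    for m in range(half + 1):
        prod = h.h[half + m] * padded[idx + m] * np.conj(padded[idx - m])
        acf[m] = prod
        if m:
            acf[n - m] = np.conj(prod)
    spec = 2.0 * np.real(np.fft.fft(acf, axis=0))
    return TfrMatrix(spec, fs=fs)  # rows = frequency, columns = time


def tfr_to_image(tfr: TfrMatrix) -> TfrImage:
    """Reduce a PWV matrix to the 45 x 150 band image.

    Rows covering 1-45 Hz are linearly interpolated onto a 1 Hz grid (row 0
    at 1 Hz), negative values are clipped to zero, and the result is min-max
    normalized; a constant matrix maps to all zeros.
    """
    freqs = tfr.freq_axis
    target = np.arange(1, IMAGE_ROWS + 1, dtype=np.float64)  # 1..45 Hz
    v = tfr.values
    band = np.empty((IMAGE_ROWS, v.shape[1]))
    for j in range(v.shape[1]):
        band[:, j] = np.interp(target, freqs, v[:, j])
    band = np.clip(band, 0.0, None)
    lo, hi = band.min(), band.max()
    if hi - lo <= 0:
        return TfrImage(np.zeros((IMAGE_ROWS, v.shape[1])))
    return TfrImage((band - lo) / (hi - lo))


def _linear_resize(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Separable linear interpolation with endpoint-aligned grids."""
    rows_in, cols_in = a.shape
    rows_out, cols_out = shape
    r_src = np.linspace(0.0, rows_in - 1, rows_out)
    c_src = np.linspace(0.0, cols_in - 1, cols_out)
    tmp = np.empty((rows_out, cols_in))
    x = np.arange(rows_in, dtype=np.float64)
    for j in range(cols_in):
        tmp[:, j] = np.interp(r_src, x, a[:, j])
    out = np.empty((rows_out, cols_out))
    x = np.arange(cols_in, dtype=np.float64)
    for i in range(rows_out):
        out[i] = np.interp(c_src, x, tmp[i])
    return out


def to_cnn_input(img: TfrImage | np.ndarray) -> np.ndarray:
    """Bilinear resize of a TFRI to the 180 x 180 classifier input."""
    a = img.pixels if isinstance(img, TfrImage) else np.asarray(img, dtype=np.float64)
    if a.shape == (CNN_INPUT_SIDE, CNN_INPUT_SIDE):
        return a
    return _linear_resize(a, (CNN_INPUT_SIDE, CNN_INPUT_SIDE))


def window_to_image(w: np.ndarray, use_hilbert: bool = True,
                    h: SmoothingKernel | None = None,
                    fs: float = WORKING_FS) -> TfrImage:
    """Full window -> TFRI transform, with or without the analytic signal.

    With ``use_hilbert`` the window is replaced by its analytic signal before
    the PWV, suppressing the mirror cross-terms a real signal produces; the
    variant without it exists for ablation.
    """
    w = np.asarray(w, dtype=np.float64)
    if w.size != WINDOW_SAMPLES:
        raise ValueError(f"expected a {WINDOW_SAMPLES}-sample window, got {w.size}")
    s = analytic_signal(w) if use_hilbert else w.astype(np.complex128)
    return tfr_to_image(pwv(s, h, fs=fs))
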