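import numpy as np
import pytest

from pwvnet.preprocess import WORKING_FS
from pwvnet.tfr import (SmoothingKernel, TfrMatrix, analytic_signal,
                        hamming_kernel, pwv, rectangular_kernel, tfr_to_image,
                        to_cnn_input, window_to_image)
from oracles import wigner_ville_direct

FS = WORKING_FS
T150 = np.arange(150) / FS


class TestSmoothingKernel:
    def test_hamming_default_is_valid(self):
        k = hamming_kernel()
        assert len(k) == 37 and k.h.max() == pytest.approx(1.0)

    @pytest.mark.parametrize("h", [np.ones(4), np.array([1.0, 0.5, 0.2]),
                                   np.array([0.5, 0.8, 0.5])])
    def test_invalid_kernels_rejected(self, h):
        with pytest.raises(ValueError):
            SmoothingKernel(h)


class TestAnalyticSignal:
    def test_real_part_exactly_preserved(self, rng):
        x = rng.normal(size=150)
        np.testing.assert_array_equal(analytic_signal(x).real, x)

    def test_negative_frequency_energy_suppressed(self):
        x = np.cos(2 * np.pi * 10.0 * T150)
        spec = np.fft.fft(analytic_signal(x))
        neg = np.sum(np.abs(spec[76:]) ** 2)
        assert neg < 1e-10 * np.sum(np.abs(spec) ** 2)

    def test_cosine_maps_to_sine_quadrature(self):
        x = np.cos(2 * np.pi * 10.0 * T150)
        a = analytic_signal(x)
        interior = slice(15, 135)
        expected = np.sin(2 * np.pi * 10.0 * T150)
        assert np.abs(a.imag[interior] - expected[interior]).max() < 0.05
        assert np.abs(np.abs(a[interior]) - 1.0).max() < 0.05

    def test_rejects_too_short_input(self):
        with pytest.raises(ValueError):
            analytic_signal(np.array([1.0]))


class TestPwv:
    def test_zero_window_gives_zero_matrix(self):
        out = pwv(np.zeros(150, dtype=complex))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_tone_concentrates_at_its_frequency(self):
        s = np.exp(2j * np.pi * 20.0 * T150)
        m = pwv(s, hamming_kernel(37))
        expected_row = int(np.argmin(np.abs(m.freq_axis - 20.0)))
        interior = m.values[:, 30:120]
        assert np.all(interior.argmax(axis=0) == expected_row)

    def test_matches_direct_definition_on_short_windows(self, rng):
        for _ in range(5):
            s = rng.normal(size=16) + 1j * rng.normal(size=16)
            k = hamming_kernel(9)
            direct = wigner_ville_direct(s, k.h)
            assert np.abs(pwv(s, k).values - direct).max() < 1e-9

    def test_time_marginal_of_unsmoothed_wv(self, rng):
        s = rng.normal(size=15) + 1j * rng.normal(size=15)
        wv = pwv(s, rectangular_kernel(15)).values
        marginal = wv.sum(axis=0)
        c = 2 * 15  # FFT column sum collapses to the zero-lag term
        rel = np.abs(marginal - c * np.abs(s) ** 2) / (c * np.abs(s) ** 2)
        assert rel.max() < 1e-6

    def test_time_shift_covariance(self, rng):
        base = rng.normal(size=150) + 1j * rng.normal(size=150)
        base[:30] = 0
        base[-30:] = 0
        d = 5
        shifted = np.roll(base, d)
        k = hamming_kernel(37)
        a = pwv(base, k).values
        b = pwv(shifted, k).values
        interior = range(40, 100)
        for n in interior:
            np.testing.assert_allclose(b[:, n + d], a[:, n], atol=1e-9)

    def test_cross_term_suppression_between_two_tones(self):
        s = np.exp(2j * np.pi * 10.0 * T150) + np.exp(2j * np.pi * 30.0 * T150)
        mid_row = int(np.argmin(np.abs(pwv(s).freq_axis - 20.0)))
        smooth = np.abs(pwv(s, hamming_kernel(37)).values[mid_row]).sum()
        rough = np.abs(pwv(s, rectangular_kernel(149)).values[mid_row]).sum()
        assert smooth < rough

    def test_rejects_oversized_kernel(self):
        with pytest.raises(ValueError):
            pwv(np.ones(16, dtype=complex), rectangular_kernel(17))


class TestTfrToImage:
    def test_zero_matrix_maps_to_zero_image(self):
        img = tfr_to_image(TfrMatrix(np.zeros((150, 150))))
        np.testing.assert_array_equal(img.pixels, 0.0)
        assert img.pixels.shape == (45, 150)

    def test_shape_and_range_contract(self, rng):
        img = tfr_to_image(TfrMatrix(rng.normal(size=(150, 150))))
        assert img.pixels.shape == (45, 150)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0

    def test_hot_row_lands_on_matching_hz_row(self):
        m = TfrMatrix(np.zeros((150, 150)))
        hot = int(np.argmin(np.abs(m.freq_axis - 10.0)))
        m.values[hot] = 1.0
        img = tfr_to_image(m)
        assert img.pixels[:, 75].argmax() == 9  # row 0 -> 1 Hz, so 10 Hz -> row 9

    def test_constant_matrix_maps_to_zeros(self):
        img = tfr_to_image(TfrMatrix(np.full((150, 150), 3.7)))
        np.testing.assert_array_equal(img.pixels, 0.0)


class TestCnnInput:
    def test_constant_image_stays_constant(self):
        img = tfr_to_image(TfrMatrix(np.zeros((150, 150))))
        img.pixels[:] = 0.0
        out = to_cnn_input(img)
        assert out.shape == (180, 180)
        np.testing.assert_allclose(out, 0.0)
        const = to_cnn_input(np.full((45, 150), 0.6))
        np.testing.assert_allclose(const, 0.6)

    def test_identity_on_native_size(self, rng):
        a = rng.random((180, 180))
        np.testing.assert_array_equal(to_cnn_input(a), a)

    def test_flattened_size_matches_dense_head(self):
        out = to_cnn_input(np.zeros((45, 150)))
        assert out.size == 32_400  # 180*180, the FC1 fan-in


class TestWindowToImage:
    def test_zero_window_zero_image_both_variants(self):
        for flag in (True, False):
            img = window_to_image(np.zeros(150), use_hilbert=flag)
            np.testing.assert_array_equal(img.pixels, 0.0)

    def test_shapes_for_both_variants(self, rng):
        w = rng.normal(size=150)
        for flag in (True, False):
            assert window_to_image(w, use_hilbert=flag).pixels.shape == (45, 150)

    def test_hilbert_suppresses_mirror_artifacts(self):
        w = np.cos(2 * np.pi * 10.0 * T150)
        band = slice(7, 12)  # rows covering 8-12 Hz
        def exterior(img):
            return img.pixels.sum() - img.pixels[band].sum()
        assert exterior(window_to_image(w, False)) > exterior(window_to_image(w, True))

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            window_to_image(np.zeros(100))
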