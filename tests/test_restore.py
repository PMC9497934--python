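"""Degradation model, adaptive denoising, PSF synthesis, Wiener inversion."""

import numpy as np
import pytest

from dqekit import (ChainConfig, DegradationModel, ImageFrame, MTFCurve,
                    degrade, denoise_adaptive, measure_mtf, psf_from_mtf,
                    simulate_edge_image, wiener_deconvolve)
from dqekit.exceptions import ConfigError

PITCH = 0.099
NYQ = 1 / (2 * PITCH)


def _gaussian_kernel(sigma_px, radius=7):
    x = np.arange(-radius, radius + 1)
    g = np.exp(-0.5 * (x / sigma_px) ** 2)
    g /= g.sum()
    return np.outer(g, g), g


def _kernel_curve(g1d):
    """Axis transfer of a separable kernel as an MTF curve (self-consistent
    reference for round-trip inversion)."""
    h = np.abs(np.fft.rfft(g1d, 4096))
    f = np.fft.rfftfreq(4096, d=PITCH)
    keep = f <= NYQ * 1.0001
    return MTFCurve(frequencies=f[keep], values=h[keep], nyquist=NYQ)


def _gaussian_curve(sigma_mm):
    f = np.linspace(0, NYQ, 102)
    return MTFCurve(frequencies=f,
                    values=np.exp(-2 * np.pi**2 * sigma_mm**2 * f**2),
                    nyquist=NYQ)


@pytest.fixture(scope="module")
def clean_edge():
    cfg = ChainConfig(fluence=5e4, pixel_pitch=PITCH, frame_shape=(256, 256),
                      seed=200, quantum_noise=False)
    return simulate_edge_image(cfg, 2.5)


class TestDegrade:
    def test_delta_kernel_is_identity(self, clean_edge):
        psf = np.zeros((5, 5))
        psf[2, 2] = 1.0
        out = degrade(clean_edge, DegradationModel(psf=psf))
        np.testing.assert_array_equal(out.pixels, clean_edge.pixels)

    def test_mean_preserved_by_unit_sum_kernel(self, clean_edge):
        psf, _ = _gaussian_kernel(1.2)
        out = degrade(clean_edge, DegradationModel(psf=psf))
        inner = (slice(16, -16),) * 2
        assert out.pixels[inner].mean() == pytest.approx(
            clean_edge.pixels[inner].mean(), rel=1e-6)

    def test_blur_lowers_half_contrast_frequency(self, clean_edge):
        psf, _ = _gaussian_kernel(1.2)
        degraded = degrade(clean_edge, DegradationModel(psf=psf))

        def mtf50(frame):
            c = measure_mtf(frame)
            return np.interp(0.5, c.values[::-1], c.frequencies[::-1])

        assert mtf50(degraded) < mtf50(clean_edge)

    def test_unnormalized_psf_rejected(self):
        with pytest.raises(ConfigError):
            DegradationModel(psf=np.full((3, 3), 0.2))

    def test_negative_psf_rejected(self):
        psf = np.full((3, 3), 1 / 9)
        psf[0, 0] = -psf[0, 0]
        with pytest.raises(ConfigError):
            DegradationModel(psf=psf / psf.sum())


class TestDenoiseAdaptive:
    def test_zero_noise_variance_is_identity(self, clean_edge):
        out = denoise_adaptive(clean_edge, window=5, noise_var=0.0)
        np.testing.assert_array_equal(out.pixels, clean_edge.pixels)

    def test_flat_noise_variance_reduction(self):
        rng = np.random.default_rng(9)
        for rep in range(20):
            noise = rng.normal(0, 4.0, (128, 128))
            frame = ImageFrame(100.0 + noise, PITCH)
            out = denoise_adaptive(frame, window=5, noise_var=16.0)
            assert out.pixels.var() < 0.2 * noise.var()

    def test_improves_rmse_on_degraded_edge(self, clean_edge):
        psf, _ = _gaussian_kernel(1.0)
        noisy = degrade(clean_edge, DegradationModel(psf=psf, noise_sigma=20.0),
                        seed=3)
        blurred = degrade(clean_edge, DegradationModel(psf=psf))
        den = denoise_adaptive(noisy, window=5)
        rmse_before = np.sqrt(np.mean((noisy.pixels - blurred.pixels) ** 2))
        rmse_after = np.sqrt(np.mean((den.pixels - blurred.pixels) ** 2))
        assert rmse_after < rmse_before

    def test_even_or_small_window_rejected(self, clean_edge):
        for window in (2, 4, 1):
            with pytest.raises(ConfigError):
                denoise_adaptive(clean_edge, window=window)


class TestPSFSynthesis:
    def test_unity_mtf_yields_delta(self):
        f = np.linspace(0, NYQ, 52)
        flat = MTFCurve(frequencies=f, values=np.ones_like(f), nyquist=NYQ)
        kernel = psf_from_mtf(flat, PITCH, support=15)
        assert kernel[7, 7] == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_round_trip_sigma(self):
        sigma = 0.08
        kernel = psf_from_mtf(_gaussian_curve(sigma), PITCH, support=15)
        xx = (np.arange(15) - 7) * PITCH
        r2 = xx[None, :] ** 2 + xx[:, None] ** 2
        keep = kernel > kernel.max() * 1e-3
        design = np.stack([np.ones(keep.sum()), -r2[keep]], axis=1)
        w = kernel[keep]
        coef, *_ = np.linalg.lstsq(design * w[:, None],
                                   np.log(kernel[keep]) * w, rcond=None)
        fitted = np.sqrt(1 / (2 * coef[1]))
        assert fitted == pytest.approx(sigma, rel=0.01)

    def test_unit_sum_contract(self):
        for sigma in (0.03, 0.08, 0.15):
            kernel = psf_from_mtf(_gaussian_curve(sigma), PITCH, support=21)
            assert kernel.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(kernel >= 0)

    def test_significantly_negative_curve_rejected(self):
        f = np.linspace(0, NYQ, 20)
        v = np.linspace(1, -0.05, 20)
        curve = MTFCurve(frequencies=f, values=v, nyquist=NYQ)
        with pytest.raises(ConfigError):
            psf_from_mtf(curve, PITCH)


class TestWiener:
    def test_near_exact_inversion_of_noiseless_blur(self, clean_edge):
        psf, g1d = _gaussian_kernel(1.0)
        degraded = degrade(clean_edge, DegradationModel(psf=psf))
        restored = wiener_deconvolve(degraded, _kernel_curve(g1d), nsr=1e-6)
        inner = (slice(20, -20),) * 2
        rmse = np.sqrt(np.mean(
            (restored.pixels[inner] - clean_edge.pixels[inner]) ** 2))
        dynamic = clean_edge.pixels.max() - clean_edge.pixels.min()
        assert rmse < 0.01 * dynamic

    def test_round_trip_various_blurs(self, clean_edge):
        inner = (slice(20, -20),) * 2
        dynamic = clean_edge.pixels.max() - clean_edge.pixels.min()
        for sigma_px in (0.7, 1.5):
            psf, g1d = _gaussian_kernel(sigma_px)
            degraded = degrade(clean_edge, DegradationModel(psf=psf))
            restored = wiener_deconvolve(degraded, _kernel_curve(g1d),
                                         nsr=1e-6)
            rmse = np.sqrt(np.mean(
                (restored.pixels[inner] - clean_edge.pixels[inner]) ** 2))
            assert rmse < 0.01 * dynamic

    def test_restores_half_contrast_frequency(self, clean_edge):
        psf, g1d = _gaussian_kernel(1.2)
        degraded = degrade(clean_edge, DegradationModel(psf=psf))
        restored = wiener_deconvolve(degraded, _kernel_curve(g1d), nsr=1e-3)

        def mtf50(frame):
            c = measure_mtf(frame)
            return np.interp(0.5, c.values[::-1], c.frequencies[::-1])

        assert mtf50(restored) > mtf50(degraded)

    def test_mean_preserved(self, clean_edge):
        psf, g1d = _gaussian_kernel(1.0)
        degraded = degrade(clean_edge, DegradationModel(psf=psf))
        restored = wiener_deconvolve(degraded, _kernel_curve(g1d), nsr=1e-2)
        assert restored.pixels.mean() == pytest.approx(
            degraded.pixels.mean(), rel=1e-3)

    def test_amplifies_high_frequency_noise(self):
        rng = np.random.default_rng(12)
        noise = ImageFrame(rng.normal(100, 3, (256, 256)), PITCH)
        restored = wiener_deconvolve(noise, _gaussian_curve(0.08), nsr=1e-4)

        def high_band_power(frame):
            spec = np.abs(np.fft.fft2(frame.pixels - frame.pixels.mean())) ** 2
            f = np.fft.fftfreq(256, d=PITCH)
            r = np.hypot(f[None, :], f[:, None])
            return spec[r > 0.7 * NYQ].mean()

        assert high_band_power(restored) > 2 * high_band_power(noise)

    def test_denoise_then_deconvolve_beats_deconvolve_alone(self, clean_edge):
        psf, g1d = _gaussian_kernel(1.0)
        curve = _kernel_curve(g1d)
        noisy = degrade(clean_edge, DegradationModel(psf=psf, noise_sigma=10.0),
                        seed=5)
        inner = (slice(20, -20),) * 2

        def rmse(frame):
            return np.sqrt(np.mean(
                (frame.pixels[inner] - clean_edge.pixels[inner]) ** 2))

        alone = rmse(wiener_deconvolve(noisy, curve, nsr=1e-2))
        chained = rmse(wiener_deconvolve(denoise_adaptive(noisy, window=5),
                                         curve, nsr=1e-2))
        assert chained < alone

    def test_ill_posed_zero_nsr_rejected(self, clean_edge):
        f = np.linspace(0, NYQ, 20)
        v = np.ones(20)
        v[-1] = 0.0
        curve = MTFCurve(frequencies=f, values=v, nyquist=NYQ)
        with pytest.raises(ConfigError):
            wiener_deconvolve(clean_edge, curve, nsr=0.0)
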