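"""Imaging-chain simulator: statistical structure and closed-form oracles."""

import numpy as np
import pytest
from scipy.stats import ttest_ind

from dqekit import (ChainConfig, PhantomLayout, ROIRect, compute_cov,
                    simulate_edge_image, simulate_flat_field,
                    simulate_phantom, theoretical_mtf, theoretical_nnps)
from dqekit.exceptions import ConfigError, LayoutError, NormalizationError
from dqekit.simulate import _edge_distance_grid
from oracles import edge_esf_oracle


class TestFlatField:
    def test_poisson_mean_and_fano_factor(self, white_flats):
        cfg, flats = white_flats
        mu = cfg.fluence * cfg.pixel_pitch**2
        pix = np.concatenate([f.pixels.ravel() for f in flats[:4]])
        assert pix.size >= 1_000_000
        se = np.sqrt(mu / pix.size)
        assert abs(pix.mean() - mu) < 5 * se
        assert pix.var() / pix.mean() == pytest.approx(1.0, abs=0.01)

    def test_zero_fluence_dark_frames(self):
        cfg = ChainConfig(fluence=0.0, pixel_pitch=0.1, frame_shape=(32, 32))
        frames = simulate_flat_field(cfg, 2)
        assert all(np.all(f.pixels == 0) for f in frames)

    def test_determinism_bit_identical(self):
        cfg = ChainConfig(fluence=1e3, pixel_pitch=0.1, blur_sigma=0.05,
                          electronic_sigma=1.0, frame_shape=(64, 64), seed=7)
        a = simulate_flat_field(cfg, 3)
        b = simulate_flat_field(cfg, 3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.pixels, fb.pixels)

    def test_frames_differ_across_indices_and_seeds(self):
        cfg = ChainConfig(fluence=1e3, pixel_pitch=0.1, frame_shape=(64, 64),
                          seed=7)
        f = simulate_flat_field(cfg, 2)
        assert not np.array_equal(f[0].pixels, f[1].pixels)
        g = simulate_flat_field(
            ChainConfig(fluence=1e3, pixel_pitch=0.1, frame_shape=(64, 64),
                        seed=8), 1)
        assert not np.array_equal(f[0].pixels, g[0].pixels)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            ChainConfig(fluence=-1, pixel_pitch=0.1)
        with pytest.raises(ConfigError):
            ChainConfig(fluence=1, pixel_pitch=0.1, frame_shape=(0, 10))
        with pytest.raises(ConfigError):
            simulate_flat_field(
                ChainConfig(fluence=1, pixel_pitch=0.1), n_frames=0)


class TestEdgeImage:
    def test_plateaus_exact_away_from_sharp_edge(self, sharp_edge_noiseless):
        cfg, edge = sharp_edge_noiseless
        level = cfg.fluence * cfg.pixel_pitch**2
        d = _edge_distance_grid(cfg.frame_shape, cfg.pixel_pitch, 2.5)
        far_dark = d < -2 * cfg.pixel_pitch
        far_bright = d > 2 * cfg.pixel_pitch
        np.testing.assert_allclose(edge.pixels[far_bright], level, rtol=1e-12)
        np.testing.assert_allclose(edge.pixels[far_dark], 0.0, atol=1e-12)

    def test_rendered_profile_matches_quadrature_oracle(
            self, blurred_edge_noiseless):
        cfg, edge = blurred_edge_noiseless
        d = _edge_distance_grid(cfg.frame_shape, cfg.pixel_pitch, 2.5)
        band = np.abs(d) < 0.6  # mm, covers the full transition
        oracle = edge_esf_oracle(d[band], cfg.pixel_pitch, 2.5,
                                 cfg.blur_sigma, 1.0)
        step = cfg.fluence * cfg.pixel_pitch**2
        dev = np.abs(edge.pixels[band] / step - oracle)
        assert dev.max() < 1e-3

    def test_partial_contrast_dark_side_level(self):
        cfg = ChainConfig(fluence=1e4, pixel_pitch=0.1, frame_shape=(128, 128),
                          quantum_noise=False)
        edge = simulate_edge_image(cfg, 2.0, edge_contrast=0.6)
        level = cfg.fluence * cfg.pixel_pitch**2
        assert edge.pixels.min() == pytest.approx(0.4 * level, rel=1e-9)

    @pytest.mark.parametrize("angle", [0.0, -1.0, 45.0, 60.0])
    def test_angle_domain(self, angle):
        cfg = ChainConfig(fluence=1e3, pixel_pitch=0.1, frame_shape=(64, 64))
        with pytest.raises(ConfigError):
            simulate_edge_image(cfg, angle)

    def test_contrast_domain(self):
        cfg = ChainConfig(fluence=1e3, pixel_pitch=0.1, frame_shape=(64, 64))
        with pytest.raises(ConfigError):
            simulate_edge_image(cfg, 2.5, edge_contrast=0.0)


class TestPhantom:
    LAYOUT = PhantomLayout(
        discs=(((128.0, 128.0), 40.0, 0.2),),
        roi_pairs=((ROIRect(112, 112, 32, 32), ROIRect(8, 8, 32, 32)),),
    )

    def test_disc_to_background_ratio_exact(self):
        cfg = ChainConfig(fluence=1e4, pixel_pitch=0.1,
                          frame_shape=(256, 256), quantum_noise=False)
        frame = simulate_phantom(cfg, self.LAYOUT)
        inner = ROIRect(112, 112, 32, 32).extract(frame)
        outer = ROIRect(8, 8, 32, 32).extract(frame)
        assert inner.mean() / outer.mean() == pytest.approx(0.8, rel=1e-12)

    def test_noiseless_cov_is_zero(self):
        cfg = ChainConfig(fluence=1e4, pixel_pitch=0.1,
                          frame_shape=(256, 256), quantum_noise=False)
        frame = simulate_phantom(cfg, self.LAYOUT)
        assert compute_cov(frame, ROIRect(8, 8, 32, 32)) == pytest.approx(
            0.0, abs=1e-12)

    def test_zero_contrast_indistinguishable_from_flat(self):
        layout = PhantomLayout(discs=(((128.0, 128.0), 40.0, 0.0),))
        cfg = ChainConfig(fluence=1e4, pixel_pitch=0.1,
                          frame_shape=(256, 256), seed=21)
        phantom = simulate_phantom(cfg, layout)
        flat = simulate_flat_field(
            ChainConfig(fluence=1e4, pixel_pitch=0.1, frame_shape=(256, 256),
                        seed=22), 1)[0]
        inside = ROIRect(96, 96, 64, 64).extract(phantom).ravel()
        outside = ROIRect(96, 96, 64, 64).extract(flat).ravel()
        assert ttest_ind(inside, outside).pvalue > 0.01

    def test_overlapping_roi_pair_rejected(self):
        with pytest.raises(LayoutError):
            PhantomLayout(roi_pairs=(
                (ROIRect(10, 10, 20, 20), ROIRect(25, 25, 20, 20)),))

    def test_disc_outside_frame_rejected(self):
        layout = PhantomLayout(discs=(((5.0, 5.0), 40.0, 0.2),))
        cfg = ChainConfig(fluence=1e3, pixel_pitch=0.1, frame_shape=(64, 64))
        with pytest.raises(LayoutError):
            simulate_phantom(cfg, layout)


class TestTheoreticalCurves:
    def test_mtf_normalized_at_zero(self):
        cfg = ChainConfig(fluence=1e3, pixel_pitch=0.1, blur_sigma=0.07)
        assert theoretical_mtf(cfg, 0.0) == 1.0

    def test_aperture_only_mtf_at_nyquist(self):
        cfg = ChainConfig(fluence=1e3, pixel_pitch=0.1, blur_sigma=0.0)
        assert theoretical_mtf(cfg, 5.0) == pytest.approx(2 / np.pi, abs=1e-12)

    def test_pure_gaussian_blur_value(self):
        # vanishing pitch: aperture sinc -> 1, leaving the Gaussian factor
        cfg = ChainConfig(fluence=1e3, pixel_pitch=1e-6, blur_sigma=0.1)
        assert theoretical_mtf(cfg, 1.0) == pytest.approx(
            np.exp(-0.19739), abs=1e-4)

    def test_blur_strictly_degrades_mtf(self):
        f = np.linspace(0.5, 5.0, 10)
        base = ChainConfig(fluence=1e3, pixel_pitch=0.1, blur_sigma=0.04)
        thick = ChainConfig(fluence=1e3, pixel_pitch=0.1, blur_sigma=0.08)
        assert np.all(theoretical_mtf(thick, f) < theoretical_mtf(base, f))

    def test_white_noise_nnps_level(self):
        cfg = ChainConfig(fluence=1e4, pixel_pitch=0.1, blur_sigma=0.0)
        f = np.linspace(0.0, 5.0, 21)
        np.testing.assert_allclose(theoretical_nnps(cfg, f), 1e-4, rtol=1e-9)

    def test_gain_cancels_when_no_electronic_noise(self):
        f = np.linspace(0.0, 5.0, 11)
        lo = ChainConfig(fluence=1e4, pixel_pitch=0.1, blur_sigma=0.05, gain=1)
        hi = ChainConfig(fluence=1e4, pixel_pitch=0.1, blur_sigma=0.05, gain=9)
        np.testing.assert_allclose(theoretical_nnps(lo, f),
                                   theoretical_nnps(hi, f), rtol=1e-12)

    def test_electronic_noise_raises_nnps_everywhere(self):
        f = np.linspace(0.0, 5.0, 11)
        quiet = ChainConfig(fluence=1e4, pixel_pitch=0.1, blur_sigma=0.05)
        noisy = ChainConfig(fluence=1e4, pixel_pitch=0.1, blur_sigma=0.05,
                            electronic_sigma=3.0)
        assert np.all(theoretical_nnps(noisy, f) > theoretical_nnps(quiet, f))

    def test_thicker_scintillator_lowers_high_frequency_quantum_noise(self):
        thin = ChainConfig(fluence=1e4, pixel_pitch=0.1, blur_sigma=0.03)
        thick = ChainConfig(fluence=1e4, pixel_pitch=0.1, blur_sigma=0.09)
        f = np.linspace(2.0, 5.0, 7)
        assert np.all(theoretical_nnps(thick, f) < theoretical_nnps(thin, f))

    def test_zero_mean_normalization_error(self):
        cfg = ChainConfig(fluence=0.0, pixel_pitch=0.1)
        with pytest.raises(NormalizationError):
            theoretical_nnps(cfg, 1.0)
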