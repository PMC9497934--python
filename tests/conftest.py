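"""Shared fixtures: simulated frames with known ground truth.

Heavy simulations are session-scoped so the suite renders each fixture once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dqekit import (ChainConfig, fluence_from_kerma, get_beam_quality,
                    simulate_edge_image, simulate_flat_field)

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

PITCH = 0.099  # mm, the high-resolution detector of the spec sheet
EDGE_ANGLE = 2.5  # degrees


@pytest.fixture(scope="session")
def sharp_edge_noiseless():
    """Noiseless unblurred edge image: ESF is the pure pixel aperture."""
    cfg = ChainConfig(fluence=1e4, pixel_pitch=PITCH, blur_sigma=0.0,
                      frame_shape=(512, 512), seed=100, quantum_noise=False)
    return cfg, simulate_edge_image(cfg, EDGE_ANGLE)


@pytest.fixture(scope="session")
def blurred_edge_noiseless():
    """Noiseless Gaussian-blurred edge image (sigma 0.08 mm)."""
    cfg = ChainConfig(fluence=1e4, pixel_pitch=PITCH, blur_sigma=0.08,
                      frame_shape=(512, 512), seed=101, quantum_noise=False)
    return cfg, simulate_edge_image(cfg, EDGE_ANGLE)


@pytest.fixture(scope="session")
def noisy_edge():
    """Quantum-noise edge image at a realistic fluence."""
    cfg = ChainConfig(fluence=1e4, pixel_pitch=PITCH, blur_sigma=0.0,
                      frame_shape=(512, 512), seed=102)
    return cfg, simulate_edge_image(cfg, EDGE_ANGLE)


@pytest.fixture(scope="session")
def white_flats():
    """Ten unblurred flat-field frames: sampled quantum noise is white."""
    cfg = ChainConfig(fluence=1e4, pixel_pitch=0.1, frame_shape=(512, 512),
                      seed=103)
    return cfg, simulate_flat_field(cfg, 10)


@pytest.fixture(scope="session")
def blurred_flats():
    """Ten blurred flat-field frames with electronic noise."""
    cfg = ChainConfig(fluence=1e4, pixel_pitch=0.1, blur_sigma=0.05,
                      electronic_sigma=2.0, frame_shape=(512, 512), seed=104)
    return cfg, simulate_flat_field(cfg, 10)


@pytest.fixture(scope="session")
def quantum_limited_chain():
    """Quantum-limited chain at the RQA-5 fluence for a 2.5 uGy kerma.

    No blur, no electronic noise, so the ideal-detector identity
    ``DQE(f -> 0) = 1`` must hold for the end-to-end pipeline.
    """
    bq = get_beam_quality("RQA5")
    kerma = 2.5
    cfg = ChainConfig(fluence=fluence_from_kerma(bq, kerma),
                      pixel_pitch=PITCH, frame_shape=(512, 512), seed=105,
                      gain=1.0)
    flats = simulate_flat_field(cfg, 10)
    edge = simulate_edge_image(cfg, EDGE_ANGLE)
    return dict(cfg=cfg, bq=bq, kerma=kerma, flats=flats, edge=edge)
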