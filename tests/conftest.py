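"""Shared fixtures: small synthetic scans and band handles."""

import numpy as np
import pytest

from ramanpen import (
    DEFAULT_BANDS,
    DepthScan,
    PreprocessConfig,
    SpectralAxis,
    SyntheticConfig,
)


@pytest.fixture(scope="session")
def bands():
    return DEFAULT_BANDS


@pytest.fixture
def small_cfg():
    """Reduced-size scan config: fast, but same physics as the defaults."""
    return SyntheticConfig(
        seed=42,
        n_lateral=6,
        n_depth=40,
        wn_step=2.0,
        noise_sd=0.1,
        spike_rate=0.0,
    )


@pytest.fixture
def small_pre_cfg():
    """Preprocess config scaled to the reduced 568-sample spectra."""
    return PreprocessConfig(shape_size=200, n_components=3)


@pytest.fixture
def flat_scan():
    """Noise-free rank-1 scan: one Gaussian band on a constant offset."""
    wn = np.arange(501.0, 1636.0, 1.0)
    band = np.exp(-0.5 * ((wn - 800.0) / 5.0) ** 2)
    depth = np.arange(10) * 0.5
    lateral = np.arange(5) * 0.5
    cube = np.tile(10.0 + 4.0 * band, (5, 10, 1))
    return DepthScan(
        axis=SpectralAxis(wn),
        lateral_positions=lateral,
        depth_positions=depth,
        intensities=cube,
    )
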