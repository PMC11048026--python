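import numpy as np
import pytest

from taskmo import (
    BackgroundSpec,
    PixelGrid,
    SignalSpecSKE,
    SignalSpecSKS,
    build_detection_dataset,
)


@pytest.fixture(scope="session")
def small_grid():
    return PixelGrid(16, 16, 0.7)


@pytest.fixture(scope="session")
def tiny_grid():
    return PixelGrid(8, 8, 0.7)


@pytest.fixture(scope="session")
def ske_spec():
    return SignalSpecSKE(amplitude=-60.0, radius=2.5)


@pytest.fixture(scope="session")
def sks_spec():
    return SignalSpecSKS(amplitude=-60.0, sigma_x=2.0, sigma_y=1.0)


@pytest.fixture(scope="session")
def corr_bg():
    return BackgroundSpec(kind="correlated-gaussian", noise_sd=42.0)


@pytest.fixture(scope="session")
def white_bg():
    return BackgroundSpec(kind="white", noise_sd=30.0)


@pytest.fixture(scope="session")
def small_dataset(small_grid, corr_bg, ske_spec):
    """16x16 SKE detection dataset with 300 pairs."""
    return build_detection_dataset(
        small_grid, corr_bg, ske_spec, n_pairs=300, seed=42
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
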