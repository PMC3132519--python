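import numpy as np
import pytest

from endoseg import PhantomConfig, generate_monolayer_phantom


@pytest.fixture(scope="session")
def standard_phantom():
    """One standard-difficulty 128x128 phantom with its ground truth."""
    cfg = PhantomConfig(width=128, height=128, n_cells=16, seed=0)
    image, mask = generate_monolayer_phantom(cfg)
    return image, mask


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Two-level phantom: no noise, gaps, speckle or illumination."""
    cfg = PhantomConfig(
        width=128, height=128, n_cells=16,
        noise_sigma=0.0, gap_fraction=0.0, speckle_density=0.0, seed=2,
    )
    image, mask = generate_monolayer_phantom(cfg)
    return image, mask, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
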