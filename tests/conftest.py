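import numpy as np
import pytest

from saccadekit.simulate import SimulationConfig, generate_scanpath


@pytest.fixture(scope="session")
def noisefree_scanpath():
    """Default 20-saccade scanpath with no measurement noise."""
    cfg = SimulationConfig(noise_sd=0.0, seed=123)
    clean, noisy, events = generate_scanpath(cfg)
    return cfg, clean, noisy, events


@pytest.fixture(scope="session")
def moderate_noise_scanpath():
    """Default scanpath with 0.5 dva white position noise."""
    cfg = SimulationConfig(noise_sd=0.5, seed=123)
    clean, noisy, events = generate_scanpath(cfg)
    return cfg, clean, noisy, events


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
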