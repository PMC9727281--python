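import numpy as np
import pytest

from srtkit.synth import SimulationConfig


@pytest.fixture
def cfg() -> SimulationConfig:
    """Default study conditions: 4 velocities x 10 trials, threshold 19 deg,
    latency 28 ms."""
    return SimulationConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def noise_rng() -> np.random.Generator:
    return np.random.default_rng(54321)
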