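import numpy as np
import pytest

from nirspeed import PipelineConfig, Recording, SimulationSpec, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rec(rng):
    """3-channel, 100-sample random recording at 10 Hz."""
    return Recording(10.0, ["ch1", "ch2", "ch3"],
                     rng.normal(size=(100, 3)), rng.normal(size=(100, 3)))


@pytest.fixture(scope="session")
def quick_spec():
    """Small simulation (6 channels, 6 trials) for pipeline-level tests."""
    return SimulationSpec(n_channels=6, n_trials=6, seed=7)


@pytest.fixture(scope="session")
def quick_sim(quick_spec):
    return generate_recording(quick_spec)


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()
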