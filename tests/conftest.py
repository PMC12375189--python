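import numpy as np
import pytest

from cagescale import FilterConfig, SimConfig, simulate_recording


@pytest.fixture(scope="session")
def default_config() -> FilterConfig:
    return FilterConfig()


@pytest.fixture(scope="session")
def short_sim():
    """A short default-condition recording with its ground truth."""
    log, truth = simulate_recording(SimConfig(duration_h=4.0), seed=11)
    return log, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
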