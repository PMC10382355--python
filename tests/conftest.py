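import numpy as np
import pytest

from hrscan import SimulationConfig, simulate_parameter_cohort


@pytest.fixture(scope="session")
def small_config():
    """A small but fully structured synthetic study configuration."""
    return SimulationConfig(
        n_tumors={"H": 4, "M": 3, "L": 3}, voxels_range=(120, 300)
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_parameter_cohort(small_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
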