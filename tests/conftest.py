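import numpy as np
import pytest

from ezmap.synthetic import (
    SimulationConfig,
    generate_connection_mask,
    generate_control_connectomes,
    generate_control_population_params,
    generate_parcellation,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_regions=12, n_controls=24, n_patients=6, seed=11)


@pytest.fixture(scope="session")
def small_parcellation(small_config):
    return generate_parcellation(small_config)


@pytest.fixture(scope="session")
def small_mask(small_config):
    return generate_connection_mask(small_config)


@pytest.fixture(scope="session")
def small_controls(small_config, small_parcellation, small_mask):
    params = generate_control_population_params(small_config, small_mask)
    return generate_control_connectomes(
        small_config, small_parcellation, small_mask, params
    )


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same stream regardless of order
    return np.random.default_rng(20230)
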