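import numpy as np
import pytest

from ugsim.city import CityGenConfig, generate_city
from ugsim.engine import SimParams
from ugsim.population import DemogConfig, generate_population


@pytest.fixture(scope="session")
def small_config():
    return CityGenConfig(
        name="testville",
        n_zones=9,
        residents_per_zone=600,
        ses_shares_city=(0.25, 0.25, 0.25, 0.25),
        segregation_strength=0.4,
        n_parks=5,
        grid_extent_m=4500.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_layout(small_config):
    return generate_city(small_config)


@pytest.fixture(scope="session")
def small_pop(small_layout):
    demog = DemogConfig(seed=5)
    params = SimParams(t_mu=0.5, ht_mu=0.5, h=0.5, seed=5)
    return generate_population(small_layout, demog, params)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
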