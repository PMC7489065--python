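import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from vmango.automata import simulate_trees
from vmango.fixtures import generate_initial_tree, generate_weather
from vmango.parameters import default_parameterization


@pytest.fixture(scope="session")
def params():
    return default_parameterization()


@pytest.fixture(scope="session")
def weather():
    return generate_weather(dt.date(2002, 7, 1), dt.date(2006, 12, 31), seed=0)


@pytest.fixture(scope="session")
def constant_weather():
    """Flat 25 degree C series for closed-form thermal-time arithmetic."""
    return generate_weather(
        dt.date(2002, 7, 1), dt.date(2006, 12, 31), mean_temp=25.0, amplitude=0.0,
        noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def ancestor_sets():
    return [generate_initial_tree(10, seed=1 + i) for i in range(3)]


@pytest.fixture(scope="session")
def sim_archs(params, weather, ancestor_sets):
    """Three trees over two growing cycles, with decision logs."""
    return simulate_trees(ancestor_sets, weather, params, 2, seed=7, grow_fruits=False)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
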