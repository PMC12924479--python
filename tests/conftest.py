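import numpy as np
import pytest

from preventure.fixtures import ratings_fixture, table2_fixture
from preventure.parameters import median_scenario
from preventure.sampling import RandomStream


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture(scope="session")
def base_scenario(table2):
    return median_scenario(table2)


@pytest.fixture(scope="session")
def ratings():
    return ratings_fixture()


@pytest.fixture()
def stream():
    return RandomStream(seed=1234, label="tests")


@pytest.fixture(scope="session")
def mc_result(table2):
    """One shared full-size Monte Carlo run (fast; reused across tests)."""
    from preventure.uncertainty import run_monte_carlo

    return run_monte_carlo(table2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260128)
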