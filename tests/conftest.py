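import numpy as np
import pytest

from crcsim.fixtures import load_fixtures
from crcsim.natural_history import Cohort


@pytest.fixture(scope="session")
def fx():
    return load_fixtures()


@pytest.fixture(scope="session")
def params(fx):
    return fx.nh_params


@pytest.fixture(scope="session")
def life_table(fx):
    return fx.life_table


@pytest.fixture(scope="session")
def small_cohort(fx):
    """4000-person cohort shared by invariant and screening tests."""
    return Cohort.generate(4000, fx.nh_params, fx.life_table, master_seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
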