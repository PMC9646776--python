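import numpy as np
import pytest

from fishclim import fixtures, niche


@pytest.fixture(scope="session")
def small_config():
    """A small, fast fixture configuration shared across the suite."""
    return fixtures.FixtureConfig(seed=11, n_lat=6, n_lon=6, n_years=25)


@pytest.fixture(scope="session")
def small_env(small_config):
    return fixtures.make_environment(small_config)


@pytest.fixture(scope="session")
def annual_k(small_env):
    return niche.annualize(niche.mdssb_daily(small_env))


@pytest.fixture(scope="session")
def grid_bbox(small_env):
    d = small_env.depth
    return (float(d["latitude"].min()), float(d["latitude"].max()),
            float(d["longitude"].min()), float(d["longitude"].max()))


@pytest.fixture(scope="session")
def k_series(annual_k, grid_bbox):
    return niche.regional_series(annual_k, grid_bbox)


@pytest.fixture(scope="session")
def stock_fixture(small_config, k_series):
    return fixtures.make_stock_series(small_config, k_series.values)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
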