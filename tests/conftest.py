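import numpy as np
import pytest

from insulametrics.island_data import load_fixture


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_df(fixture_table):
    return fixture_table.to_dataframe()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240217)
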