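import numpy as np
import pytest

from olfscreen.synthetic_data import load_agonist_fixture


@pytest.fixture(scope="session")
def agonist_fixture():
    return load_agonist_fixture()


@pytest.fixture(scope="session")
def fixture_compounds(agonist_fixture):
    return agonist_fixture.compounds()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
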