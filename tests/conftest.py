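import pytest

from betatopo.datamodel import ModelConfig
from betatopo.fixtures import make_fixture


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def fx3():
    return make_fixture(3, seed=11)


@pytest.fixture(scope="session")
def fx4():
    return make_fixture(4, seed=1)


@pytest.fixture(scope="session")
def fx5():
    return make_fixture(5, seed=3)
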