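import pytest

from walklink.synthetic import fixture_graphs


@pytest.fixture(scope="session")
def fixtures():
    return fixture_graphs()


@pytest.fixture
def path4(fixtures):
    return fixtures["path4"]


@pytest.fixture
def triangle(fixtures):
    return fixtures["triangle"]


@pytest.fixture
def single_edge(fixtures):
    return fixtures["single_edge"]
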