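import pytest

from pedbreed.synthetic_germplasm import fixture_suite


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def trio(fixtures):
    return fixtures["trio"]


@pytest.fixture(scope="session")
def backcross(fixtures):
    return fixtures["backcross"]


@pytest.fixture(scope="session")
def germplasm50(fixtures):
    return fixtures["germplasm50"]
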