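import pytest

from hoclust import build_catalog, toy_networks


@pytest.fixture(scope="session")
def catalog():
    return build_catalog(5)


@pytest.fixture(scope="session")
def catalog4():
    return build_catalog(4)


@pytest.fixture()
def toys():
    return toy_networks()
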