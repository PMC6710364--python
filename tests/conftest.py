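import pytest

from boolfuzz import load_fixture


@pytest.fixture(scope="session")
def bpc():
    return load_fixture("bpc")


@pytest.fixture(scope="session")
def nfkb():
    return load_fixture("nfkb")


@pytest.fixture(scope="session")
def toggle():
    return load_fixture("toggle")


@pytest.fixture(scope="session")
def negring3():
    return load_fixture("negring3")


def state_of(net, **levels):
    """Full state tuple in node order, defaulting unlisted nodes to 0."""
    return tuple(int(levels.get(name, 0)) for name in net.nodes)
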