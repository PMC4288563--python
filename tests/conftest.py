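import pytest

from linframe import build_graph, build_pho5_graph, pho5_transcribing_indicator
from linframe.grf import rational_grf


@pytest.fixture(scope="session")
def pho5_graph():
    return build_pho5_graph("LH")


@pytest.fixture(scope="session")
def pho5_grf(pho5_graph):
    """Symbolic PHO5 regulation function; computed once per session
    because it enumerates all 53,376 spanning trees."""
    return rational_grf(pho5_graph, pho5_transcribing_indicator(pho5_graph))


@pytest.fixture
def two_state():
    """The smallest reversible graph: 1 <-> 2 with labels a, b."""
    return build_graph(2, [(1, 2, "a"), (2, 1, "b")])


@pytest.fixture
def three_cycle():
    """Irreversible 3-cycle 1 -> 2 -> 3 -> 1 with labels a, b, c."""
    return build_graph(3, [(1, 2, "a"), (2, 3, "b"), (3, 1, "c")])


@pytest.fixture
def chain():
    """Irreversible chain 1 -> 2 -> 3; only {3} is terminal."""
    return build_graph(3, [(1, 2, "a"), (2, 3, "b")])
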