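import pytest

from snarlmap.distance import build_distance_index
from snarlmap.sim import random_variation_graph
from snarlmap.snarls import decompose
from snarlmap.toys import g1, g2, g3


@pytest.fixture
def G1():
    return g1()


@pytest.fixture
def G2():
    return g2()


@pytest.fixture
def G3():
    return g3()


@pytest.fixture
def G1_index(G1):
    return build_distance_index(G1, decompose(G1))


@pytest.fixture
def G2_index(G2):
    return build_distance_index(G2, decompose(G2))


@pytest.fixture
def G3_index(G3):
    return build_distance_index(G3, decompose(G3))


@pytest.fixture
def random_graph():
    """Factory for small random variation graphs."""

    def make(seed, max_nodes=30):
        return random_variation_graph(seed, max_nodes=max_nodes)

    return make
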