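from pathlib import Path

import pytest

from seedwalk import Network, Partition, read_graph, read_membership

DATA = Path(__file__).parent / "data"


def clique_edges(names):
    return [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]


@pytest.fixture
def triangle():
    return Network(edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return Network(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def star5():
    return Network(edges=[("c", f"l{i}") for i in range(4)])


@pytest.fixture
def two_cliques5():
    """Two 5-cliques joined by a single bridge edge."""
    a = [f"a{i}" for i in range(5)]
    b = [f"b{i}" for i in range(5)]
    return Network(edges=clique_edges(a) + clique_edges(b) + [("a0", "b0")])


@pytest.fixture
def two_cliques4():
    a = [f"a{i}" for i in range(4)]
    b = [f"b{i}" for i in range(4)]
    return Network(edges=clique_edges(a) + clique_edges(b) + [("a0", "b0")])


@pytest.fixture
def karate():
    net = read_graph(DATA / "karate.edgelist")
    truth = Partition(read_membership(DATA / "karate.truth.tsv"))
    return net, truth
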