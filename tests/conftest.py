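import networkx as nx
import pytest

from capnet.synthetic_networks import fixture_26sn


@pytest.fixture(scope="session")
def fixture_net():
    return fixture_26sn()


@pytest.fixture
def star5():
    """Undirected 5-node star; center 'c', leaves l1..l4."""
    g = nx.Graph()
    g.add_edges_from(("c", f"l{i}") for i in range(1, 5))
    return g


@pytest.fixture
def two_cliques_bridged():
    """Two 4-cliques joined by one edge a1–b1."""
    g = nx.Graph()
    for labels in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        g.add_edges_from(
            (labels[i], labels[j]) for i in range(4) for j in range(i + 1, 4)
        )
    g.add_edge("a1", "b1")
    return g


def random_graphs(count, max_nodes=12, seed0=1000, directed_every=2):
    """Seeded stream of small random graphs, alternating undirected/directed."""
    import random

    graphs = []
    for i in range(count):
        rng = random.Random(seed0 + i)
        n = rng.randint(4, max_nodes)
        p = rng.uniform(0.15, 0.6)
        directed = i % directed_every == 1
        g = nx.gnp_random_graph(n, p, seed=seed0 + i, directed=directed)
        graphs.append(g)
    return graphs
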