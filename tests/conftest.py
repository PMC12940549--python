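import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from keynet.datatypes import WeightedNetwork

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def triangle() -> WeightedNetwork:
    return WeightedNetwork.from_edges([("A", "B", 500), ("B", "C", 600), ("A", "C", 700)])


@pytest.fixture
def star5() -> WeightedNetwork:
    """Star with center HUB and five leaves."""
    return WeightedNetwork.from_edges(
        [("HUB", f"L{i}", 100 * i + 100) for i in range(1, 6)]
    )


@pytest.fixture
def path3() -> WeightedNetwork:
    return WeightedNetwork.from_edges([("A", "B", 400), ("B", "C", 500)])


def random_network(n: int, p: float, seed: int) -> WeightedNetwork:
    """Erdos-Renyi G(n, p) with random integer scores; at least one edge."""
    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    if g.number_of_edges() == 0:
        g.add_edge(0, 1)
    edges = [
        (f"N{u:02d}", f"N{v:02d}", int(rng.integers(1, 1001)))
        for u, v in g.edges()
    ]
    return WeightedNetwork.from_edges(edges, nodes=[f"N{i:02d}" for i in range(n)])


@pytest.fixture
def random_net() -> WeightedNetwork:
    return random_network(12, 0.35, seed=7)
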