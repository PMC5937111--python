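import networkx as nx
import pytest

from ppiscreen import InteractionNetwork, SyntheticSpec, generate_interactome


def net_from(graph: nx.Graph, seeds=()) -> InteractionNetwork:
    """Wrap a networkx graph with string node labels."""
    g = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    return InteractionNetwork(g, {n: n in set(seeds) for n in g.nodes})


@pytest.fixture
def star5() -> InteractionNetwork:
    return net_from(nx.star_graph(5))  # center "0", leaves "1".."5"


@pytest.fixture
def path4() -> InteractionNetwork:
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture(scope="session")
def default_instance():
    """One full synthetic study instance (seed 1), shared across tests."""
    spec = SyntheticSpec(rng_seed=1)
    return spec, generate_interactome(spec)
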