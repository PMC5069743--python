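import networkx as nx
import numpy as np
import pytest

from hpinet import GeneSet, Network, SyntheticScenario, generate_scenario


def make_network(edges, extra_nodes=()) -> Network:
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return Network(g)


def gene_set(name, role, nodes) -> GeneSet:
    return GeneSet.from_nodes(name, role, nodes)


def random_small_network(rng: np.random.Generator, max_nodes: int = 8) -> Network:
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.2, 0.8))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return Network(nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)}))


@pytest.fixture
def path6() -> Network:
    # a-b-c-d-e-f
    return make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f")])


@pytest.fixture
def star4() -> Network:
    return make_network([("x", "l1"), ("x", "l2"), ("x", "l3"), ("x", "l4")])


@pytest.fixture(scope="session")
def default_scenario():
    return generate_scenario(SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def small_scenario():
    # desk-scale scenario for fast end-to-end checks
    return generate_scenario(
        SyntheticScenario(
            seed=7, n_nodes=400, er_edge_prob=0.02, target_module_size=20,
            required_size=50, essential_size=60, n_complexes=20,
            complex_size_range=(3, 5), tf_size=25, enzyme_size=20,
        )
    )
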