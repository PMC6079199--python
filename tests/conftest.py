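import networkx as nx
import numpy as np
import pytest

from mutnet.reaction_net import MetaboliteNetwork
from mutnet import synthetic_data as synth


def net_from_edges(edges, nodes=None):
    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, reactions=(f"R_{u}_{v}",))
    return MetaboliteNetwork(graph=g)


@pytest.fixture
def path_abc():
    """Directed path a -> b -> c."""
    return net_from_edges([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def fixture_graphs():
    """Small named digraphs (<= 8 nodes) for oracle comparisons."""
    rng = np.random.default_rng(11)
    graphs = {
        "path4": [("a", "b"), ("b", "c"), ("c", "d")],
        "cycle4": [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")],
        "outstar": [("h", x) for x in "abcd"],
        "diamond": [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")],
        "twin_paths": [("a", "b"), ("b", "d"), ("a", "c"), ("c", "d"), ("d", "e")],
    }
    for i in range(4):
        n = int(rng.integers(5, 9))
        labels = [chr(ord("a") + k) for k in range(n)]
        edges = set()
        for _ in range(int(rng.integers(n, 3 * n))):
            u, v = rng.choice(n, size=2, replace=False)
            edges.add((labels[u], labels[v]))
        graphs[f"random{i}"] = sorted(edges)
    return {
        name: net_from_edges(edges, nodes=sorted({x for e in edges for x in e}))
        for name, edges in graphs.items()
    }


@pytest.fixture(scope="session")
def sim_experiment():
    """One simulated 12-metabolite MA experiment shared across tests."""
    net = synth.generate_toy_network(12, 1.6, seed=7)
    cfg = synth.SimConfig(n_lines=25, seed=7)
    table, truth = synth.simulate_MA(cfg, net)
    return net, cfg, table, truth
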