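import networkx as nx
import numpy as np
import pytest

from ppiflow.maxnet import FlowNetwork


@pytest.fixture
def triangle():
    return nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3():
    return nx.Graph([("A", "B"), ("B", "C")])


@pytest.fixture
def star4():
    """Star with centre 'C' and four leaves."""
    return nx.Graph([("C", "L1"), ("C", "L2"), ("C", "L3"), ("C", "L4")])


@pytest.fixture
def diamond_network():
    """Classic 6-node flow network with max flow 13."""
    arcs = {
        ("S", "a"): 10.0,
        ("S", "b"): 10.0,
        ("a", "b"): 2.0,
        ("a", "T"): 4.0,
        ("b", "T"): 9.0,
    }
    return FlowNetwork(nodes={"S", "a", "b", "T"}, arcs=arcs, source="S", sink="T")


def random_flow_network(rng: np.random.Generator, n_nodes: int = 12, p: float = 0.35) -> FlowNetwork:
    """A random directed flow network with real capacities in [0, 2]."""
    names = [f"n{i}" for i in range(n_nodes)]
    arcs = {}
    for u in names:
        for v in names:
            if u != v and rng.random() < p:
                arcs[(u, v)] = float(rng.uniform(0, 2))
    source, sink = names[0], names[-1]
    arcs = {(u, v): c for (u, v), c in arcs.items() if v != source and u != sink}
    return FlowNetwork(nodes=set(names), arcs=arcs, source=source, sink=sink)
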