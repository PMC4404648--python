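import random

import pytest

from hsmnet import DirectedNetwork, generate_perfect_hierarchy


@pytest.fixture
def military():
    """Perfect 5-level, 19-node command tree with known truth."""
    return generate_perfect_hierarchy(seed=11)


@pytest.fixture
def toy_net():
    """Small 6-node network with cycles, amenable to exhaustive search."""
    return DirectedNetwork.from_edges([
        ("a", "b"), ("a", "c"), ("b", "d"), ("c", "d"),
        ("d", "e"), ("e", "f"), ("f", "a"), ("c", "f"),
    ])


def random_digraph(rng: random.Random, n_nodes: int,
                   p_edge: float = 0.3, self_loops: bool = False
                   ) -> DirectedNetwork:
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [(u, v) for u in nodes for v in nodes
             if (self_loops or u != v) and rng.random() < p_edge]
    if not edges:  # keep HS defined
        edges = [(nodes[0], nodes[-1])]
    return DirectedNetwork(nodes, edges)
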