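import logging

import networkx as nx
import numpy as np
import pytest

from edgcsn.io_formats import GeneNetwork
from edgcsn.synthetic import worked_example

logging.getLogger("edgcsn").setLevel(logging.ERROR)


@pytest.fixture
def bundle():
    """The hand-computed 8-gene worked example."""
    return worked_example()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_network(rng, n_max=8, p=0.35, kind="fused"):
    """A random simple graph over letter-named nodes (edges only)."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in range(n)})
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        g.add_edge("N0", "N1")
    return GeneNetwork(g.copy(), kind=kind)
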