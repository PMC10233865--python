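import numpy as np
import pytest

import herblink as hb
from herblink.network import Fingerprint, HetGraph, LayeredEdge, NodeMeta


def chem_graph(edges, extra_nodes=()):
    """Arbitrary-topology helper graph: every node a drug chemical, every
    edge a CCC edge. Lets index/walk tests use any structure without
    fighting the layer role typing."""
    nodes = {n for e in edges for n in e} | set(extra_nodes)
    meta = [NodeMeta(n, "chemical", frozenset({"drug"})) for n in sorted(nodes)]
    return HetGraph(meta, [LayeredEdge(u, v, "CCC") for u, v in edges])


def random_chem_graph(rng, n_max=30, p=0.15):
    n = int(rng.integers(5, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return chem_graph(edges, extra_nodes=nodes)


@pytest.fixture(scope="session")
def tiny_net():
    return hb.generate(hb.TINY_PROFILE)


@pytest.fixture(scope="session")
def tiny_layers(tiny_net):
    return tiny_net.build_layers()


@pytest.fixture(scope="session")
def tiny_graph_full(tiny_net, tiny_layers):
    spec = hb.DatasetSpec("DS-CX-drug", frozenset({"CTC", "CCC", "PPI"}))
    return hb.assemble_dataset(spec, tiny_layers, tiny_net.meta)


@pytest.fixture(scope="session")
def tiny_graph_ctc(tiny_net, tiny_layers):
    spec = hb.DatasetSpec("DS-CX-drug", frozenset({"CTC"}))
    return hb.assemble_dataset(spec, {"CTC": tiny_layers["CTC"]}, tiny_net.meta)


#: fast node2vec training parameters for test-scale graphs
FAST_N2V = hb.Node2vecParams(dims=64, walk_length=40, walks_per_node=5, window=5, epochs=2)
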