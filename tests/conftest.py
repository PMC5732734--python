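"""Shared fixtures: tiny hand-built networks, random weighted networks,
and the session-scoped planted-module benchmark."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netprior.network import WeightedNetwork
from netprior.synthetic import SyntheticSpec, generate


def make_net(edges, seeds=(), node_weights=None, edge_weights=None) -> WeightedNetwork:
    """Build a WeightedNetwork from (a, b) pairs; weights default to 1."""
    g = nx.Graph()
    node_weights = node_weights or {}
    edge_weights = edge_weights or {}
    for a, b in edges:
        g.add_edge(a, b, weight=float(edge_weights.get((a, b), edge_weights.get((b, a), 1.0))))
    for n in g.nodes:
        g.nodes[n]["weight"] = float(node_weights.get(n, 1.0))
        g.nodes[n]["is_seed"] = n in set(seeds)
    return WeightedNetwork(graph=g)


def random_connected_network(
    rng: np.random.Generator, n_min: int = 5, n_max: int = 50, p: float = 0.3
) -> WeightedNetwork:
    """A random connected undirected network with random positive weights."""
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if nx.is_connected(g):
            break
    out = nx.Graph()
    for i in g.nodes:
        out.add_node(f"N{i:03d}", weight=float(rng.random() + 0.01), is_seed=False)
    for a, b in g.edges:
        out.add_edge(f"N{a:03d}", f"N{b:03d}", weight=float(rng.random() + 0.01))
    return WeightedNetwork(graph=out)


@pytest.fixture(scope="session")
def planted():
    """The default planted-module benchmark instance (rng seed 42)."""
    return generate(SyntheticSpec())


@pytest.fixture()
def triangle():
    return make_net([("A", "B"), ("B", "C"), ("A", "C")], seeds=("A",))
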