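"""Disease-related subnetwork construction.

The disease network is the subgraph induced by the seed (disease) genes
present in the source interaction network plus all of their direct
interactors.  Keeping the *induced* subgraph (including edges between two
non-seed interactors) preserves candidate-candidate paths, which the
propagation step needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx

from .io import EdgeRecord

logger = logging.getLogger(__name__)


@dataclass
class WeightedNetwork:
    """Undirected gene network with per-node and per-edge weights.

    Node attributes: ``weight`` (w_g >= 0) and ``is_seed``; edge
    attribute: ``weight`` (w(h,g) >= 0, symmetric because the graph is
    undirected).  ``missing_seeds`` records seed symbols that were not
    found in the interaction universe; they are kept for cross-validation
    bookkeeping but are not nodes.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    missing_seeds: tuple[str, ...] = ()

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def seeds(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if self.graph.nodes[n]["is_seed"])

    @property
    def candidates(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if not self.graph.nodes[n]["is_seed"])

    def node_weight(self, g: str) -> float:
        return self.graph.nodes[g]["weight"]

    def edge_weight(self, h: str, g: str) -> float:
        return self.graph.edges[h, g]["weight"]

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(graph=self.graph.copy(), missing_seeds=self.missing_seeds)

    def validate(self) -> None:
        for n, d in self.graph.nodes(data=True):
            if d["weight"] < 0:
                raise ValueError(f"negative node weight on {n}")
        for a, b, d in self.graph.edges(data=True):
            if d["weight"] < 0:
                raise ValueError(f"negative edge weight on ({a},{b})")
        if self.graph.number_of_nodes() and not any(
            d["weight"] > 0 for _, d in self.graph.nodes(data=True)
        ):
            raise ValueError("all node weights are zero")


class NetworkSummary(NamedTuple):
    n_nodes: int
    n_edges: int
    n_seeds: int
    n_candidates: int
    n_components: int


def build_disease_subnetwork(
    edges: Iterable[EdgeRecord], seeds: Sequence[str]
) -> WeightedNetwork:
    """Build the disease network: seeds plus their direct interactors.

    The node set is the seeds found in the edge universe together with
    all of their neighbors; the edge set is every source edge with both
    endpoints in that node set (induced subgraph).  All weights start at
    1 pending functional weighting.  Seeds absent from the universe are
    reported on ``missing_seeds``, not fatal.

    Raises
    ------
    ValueError
        if no seed appears in the edge universe.
    """
    src = nx.Graph()
    for rec in edges:
        src.add_edge(rec.gene_a, rec.gene_b)

    seed_list = list(dict.fromkeys(seeds))
    present = [s for s in seed_list if s in src]
    missing = tuple(s for s in seed_list if s not in src)
    if not present:
        raise ValueError("no seed in network: none of the seed genes appears "
                         "in the interaction universe")
    if missing:
        logger.warning("%d seed gene(s) absent from the interaction universe: %s",
                       len(missing), ", ".join(missing))

    keep: set[str] = set(present)
    for s in present:
        keep.update(src.neighbors(s))

    sub = nx.Graph()
    seed_set = set(present)
    for n in keep:
        sub.add_node(n, weight=1.0, is_seed=n in seed_set)
    for a, b in src.edges:
        if a in keep and b in keep:
            sub.add_edge(a, b, weight=1.0)
    return WeightedNetwork(graph=sub, missing_seeds=missing)


def network_summary(net: WeightedNetwork) -> NetworkSummary:
    g = net.graph
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_seeds=len(net.seeds),
        n_candidates=len(net.candidates),
        n_components=nx.number_connected_components(g) if g.number_of_nodes() else 0,
    )
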