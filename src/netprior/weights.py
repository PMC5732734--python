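"""Functional weighting of nodes and edges from shared annotations.

Both node weights w_g and edge weights w(h,g) are derived from the
Jaccard index between (optionally ancestor-closed) term sets: an edge is
weighted by the similarity of its endpoints' annotations, and a candidate
gene by its similarity to the most similar seed (or to the seed average).
Seeds themselves carry maximal node weight 1, so initial disease risk
concentrates on the known disease genes.  A small positive floor keeps
every weight strictly positive by default: a zero-weight column would
leave the risk-transition matrix undefined for that gene.

All three ontology aspects are pooled into a single term set by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import AnnotationMap
from .network import WeightedNetwork

EDGE_SCHEMES = ("jaccard",)
NODE_SCHEMES = ("max-sim-to-seeds", "mean-sim-to-seeds")
UNANNOTATED_POLICIES = ("floor", "zero")


@dataclass
class WeightingConfig:
    edge_scheme: str = "jaccard"
    node_scheme: str = "max-sim-to-seeds"
    epsilon_floor: float = 0.001
    unannotated_policy: str = "floor"

    def __post_init__(self) -> None:
        if self.edge_scheme not in EDGE_SCHEMES:
            raise ValueError(f"unknown edge scheme {self.edge_scheme!r}")
        if self.node_scheme not in NODE_SCHEMES:
            raise ValueError(f"unknown node scheme {self.node_scheme!r}")
        if not 0.0 < self.epsilon_floor < 1.0:
            raise ValueError("epsilon_floor must lie strictly between 0 and 1")
        if self.unannotated_policy not in UNANNOTATED_POLICIES:
            raise ValueError(f"unknown unannotated policy {self.unannotated_policy!r}")


def term_set_similarity(terms_a: set[str], terms_b: set[str]) -> float:
    """Jaccard index |A∩B| / |A∪B|; 0 when both sets are empty."""
    if not terms_a and not terms_b:
        return 0.0
    inter = len(terms_a & terms_b)
    if inter == 0:
        return 0.0
    return inter / len(terms_a | terms_b)


def _terms(ann: AnnotationMap | dict, gene: str) -> set[str]:
    if isinstance(ann, AnnotationMap):
        return ann.terms(gene)
    return ann.get(gene, set())


def _apply_policy(sim: float, cfg: WeightingConfig) -> float:
    if cfg.unannotated_policy == "floor":
        return max(sim, cfg.epsilon_floor)
    return sim


def assign_edge_weights(
    net: WeightedNetwork, ann: AnnotationMap | dict, cfg: WeightingConfig | None = None
) -> WeightedNetwork:
    """Weight each edge by the functional similarity of its endpoints.

    Returns a new network; the input is not modified.  Symmetry holds by
    construction because edges are undirected.
    """
    cfg = cfg or WeightingConfig()
    out = net.copy()
    for h, g in out.graph.edges:
        sim = term_set_similarity(_terms(ann, h), _terms(ann, g))
        out.graph.edges[h, g]["weight"] = _apply_policy(sim, cfg)
    return out


def assign_node_weights(
    net: WeightedNetwork,
    ann: AnnotationMap | dict,
    seeds: Sequence[str],
    cfg: WeightingConfig | None = None,
) -> WeightedNetwork:
    """Weight each gene by its functional similarity to the seed set.

    Genes in ``seeds`` get weight 1; every other gene gets the maximum
    (or mean, under ``mean-sim-to-seeds``) Jaccard similarity between its
    term set and each seed's, floored according to the policy.  The
    ``seeds`` argument - not the network's seed flags - defines the seed
    set, so cross-validation can re-weight with a reduced list while the
    topology stays fixed.
    """
    cfg = cfg or WeightingConfig()
    seed_set = {s for s in seeds if s in net.graph}
    if not seed_set:
        raise ValueError("no seed gene present in the network")
    out = net.copy()
    seed_terms = {s: _terms(ann, s) for s in sorted(seed_set)}
    for g in out.graph.nodes:
        if g in seed_set:
            out.graph.nodes[g]["weight"] = 1.0
            continue
        g_terms = _terms(ann, g)
        sims = [term_set_similarity(g_terms, ts) for s, ts in seed_terms.items() if s != g]
        if cfg.node_scheme == "max-sim-to-seeds":
            sim = max(sims) if sims else 0.0
        else:
            sim = sum(sims) / len(sims) if sims else 0.0
        out.graph.nodes[g]["weight"] = _apply_policy(sim, cfg)
    return out


def assign_uniform_weights(net: WeightedNetwork) -> WeightedNetwork:
    """Set every node and edge weight to 1 (the unweighted baseline)."""
    out = net.copy()
    for n in out.graph.nodes:
        out.graph.nodes[n]["weight"] = 1.0
    for h, g in out.graph.edges:
        out.graph.edges[h, g]["weight"] = 1.0
    return out
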