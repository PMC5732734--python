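"""Leave-one-out cross-validation and rank-based ROC/AUC.

Each seed gene is held out in turn and re-ranked as if unknown.  Under
the default ``topology="rebuild"`` protocol the disease subnetwork is
rebuilt from the remaining seeds, so the held-out gene enters — if at
all — as an ordinary candidate recruited by the other seeds.  A fold
whose held-out gene drops out of the rebuilt network (it interacts with
no remaining seed) is recorded and excluded: such a gene could never be
ranked by the method, and scoring it any other way leaks information.
The alternative ``topology="fixed"`` protocol keeps the network built
from the full seed set and only rebuilds node weights (and hence the
initial vector) per fold; it keeps every fold evaluable but is
optimistically biased, because the held-out seed retains the
neighborhood that only its own seed status pulled into the network.

The ROC treats each fold as one positive competing against the
``pool_size - 1`` negatives of its own pool.  Ranks are mapped to the
normalized scale x = (rank - 1)/(pool_size - 1), the fraction of the
pool's negatives ranked above the positive; the curve is TPR(t) =
fraction of folds with x <= t against FPR(t) = t, and its trapezoidal
area equals the fold-averaged Mann-Whitney statistic
mean((pool_size - rank)/(pool_size - 1)) exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

from .io import AnnotationMap
from .network import WeightedNetwork
from .propagation import (
    PropagationConfig,
    RankedGene,
    build_transition_matrix,
    initial_scores,
    propagate,
)
from .weights import (
    WeightingConfig,
    assign_edge_weights,
    assign_node_weights,
    assign_uniform_weights,
)

logger = logging.getLogger(__name__)


class FoldRecord(NamedTuple):
    held_out_gene: str
    rank: int
    pool_size: int


@dataclass
class LoocvResult:
    folds: list[FoldRecord]
    roc_points: list[tuple[float, float]]
    auc: float
    excluded: list[str] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def roc_from_ranks(
    folds: Sequence[tuple[int, int] | FoldRecord],
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC from held-out (rank, pool_size) records.

    The AUC equals the fold-averaged fraction of pool negatives ranked
    below the held-out gene (the Mann-Whitney statistic with every fold
    weighted equally); the trapezoidal rule over the returned points
    reproduces it exactly because TPR is piecewise constant in FPR.
    """
    if not folds:
        raise ValueError("empty fold list")
    xs = []
    for rec in folds:
        if isinstance(rec, FoldRecord):
            rank, pool = rec.rank, rec.pool_size
        else:
            rank, pool = int(rec[0]), int(rec[1])
        if pool < 2:
            raise ValueError(f"pool size {pool} too small for a rank-based ROC")
        if not 1 <= rank <= pool:
            raise ValueError(f"rank {rank} outside [1, {pool}]")
        xs.append((rank - 1) / (pool - 1))
    xs = np.sort(np.asarray(xs, dtype=float))
    n = len(xs)

    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tpr = 0.0
    for v in np.unique(xs):
        count = float(np.sum(xs == v))
        if v > 0.0 and points[-1][0] < v:
            points.append((float(v), tpr))  # horizontal run at current TPR
        tpr += count / n
        points.append((float(v), tpr))  # vertical jump at the breakpoint
    if points[-1][0] < 1.0:
        points.append((1.0, 1.0))

    fpr_arr = np.array([p[0] for p in points])
    tpr_arr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return points, auc


def _fold_network(
    edges, ann, fold_seeds: list[str], wcfg: WeightingConfig, weighting: str
) -> WeightedNetwork:
    from .network import build_disease_subnetwork

    net = build_disease_subnetwork(edges, fold_seeds)
    if weighting == "uniform":
        return assign_uniform_weights(net)
    net = assign_edge_weights(net, ann, wcfg)
    return assign_node_weights(net, ann, fold_seeds, wcfg)


def loocv(
    edges,
    ann: AnnotationMap | dict,
    seeds: Sequence[str],
    pcfg: Optional[PropagationConfig] = None,
    wcfg: Optional[WeightingConfig] = None,
    weighting: str = "functional",
    topology: str = "rebuild",
) -> LoocvResult:
    """Leave-one-out cross-validation of the prioritizer.

    ``edges`` is the source edge list (the network-building input, not a
    prebuilt subnetwork).  For each seed s present in the edge universe
    the seed set is reduced by s and s is re-ranked among the candidate
    pool; see the module docstring for the ``rebuild`` (default) versus
    ``fixed`` topology protocols.  ``weighting`` selects the functional
    scheme (default) or the ``uniform`` baseline in which every node and
    edge weight is 1.

    Raises
    ------
    ValueError
        with fewer than two seeds present in the edge universe, or if no
        fold is evaluable.
    """
    pcfg = pcfg or PropagationConfig()
    wcfg = wcfg or WeightingConfig()
    if weighting not in ("functional", "uniform"):
        raise ValueError(f"unknown weighting mode {weighting!r}")
    if topology not in ("rebuild", "fixed"):
        raise ValueError(f"unknown topology mode {topology!r}")

    universe: set[str] = set()
    for rec in edges:
        universe.add(rec.gene_a)
        universe.add(rec.gene_b)
    present_seeds = [s for s in seeds if s in universe]
    if len(present_seeds) < 2:
        raise ValueError("need at least two seeds present in the network for LOOCV")

    folds: list[FoldRecord] = []
    excluded: list[str] = []

    if topology == "fixed":
        base = _fold_network(edges, ann, present_seeds, wcfg, weighting)
        Q = build_transition_matrix(base)
        candidates = list(base.candidates)
        for s in present_seeds:
            if base.graph.degree(s) == 0:
                logger.warning("held-out seed %s is isolated; fold excluded", s)
                excluded.append(s)
                continue
            reduced = [t for t in present_seeds if t != s]
            if weighting == "functional":
                fold_net = assign_node_weights(base, ann, reduced, wcfg)
            else:
                fold_net = base  # uniform weights do not depend on the seed set
            scores, _ = propagate(Q, initial_scores(fold_net), pcfg)
            score_of = dict(zip(fold_net.nodes, scores))
            pool = sorted([s, *candidates], key=lambda g: (-score_of[g], g))
            folds.append(FoldRecord(s, pool.index(s) + 1, len(pool)))
    else:
        for s in present_seeds:
            reduced = [t for t in present_seeds if t != s]
            try:
                fold_net = _fold_network(edges, ann, reduced, wcfg, weighting)
            except ValueError:
                logger.warning("no remaining seed in the network when holding "
                               "out %s; fold excluded", s)
                excluded.append(s)
                continue
            if s not in fold_net.graph:
                logger.warning("held-out seed %s interacts with no remaining "
                               "seed; fold excluded", s)
                excluded.append(s)
                continue
            Q = build_transition_matrix(fold_net)
            scores, _ = propagate(Q, initial_scores(fold_net), pcfg)
            score_of = dict(zip(fold_net.nodes, scores))
            pool = sorted(fold_net.candidates, key=lambda g: (-score_of[g], g))
            folds.append(FoldRecord(s, pool.index(s) + 1, len(pool)))

    if not folds:
        raise ValueError("no evaluable LOOCV fold")
    points, auc = roc_from_ranks(folds)
    return LoocvResult(folds=folds, roc_points=points, auc=auc, excluded=excluded)


def loocv_auc_evaluator(
    edges,
    ann: AnnotationMap | dict,
    seeds: Sequence[str],
    wcfg: Optional[WeightingConfig] = None,
    weighting: str = "functional",
    topology: str = "rebuild",
    tolerance: float = 1e-9,
) -> Callable[[float], float]:
    """Factory for a beta -> LOOCV AUC evaluator (for beta sweeps)."""
    edges = list(edges)

    def _eval(beta: float) -> float:
        cfg = PropagationConfig(beta=beta, tolerance=tolerance)
        return loocv(edges, ann, seeds, cfg, wcfg,
                     weighting=weighting, topology=topology).auc

    return _eval


def baseline_rankers(
    net: WeightedNetwork, pcfg: Optional[PropagationConfig] = None
) -> dict[str, list[RankedGene]]:
    """Candidate rankings for simple comparison baselines.

    ``degree``: plain interaction count; ``weighted-degree``: sum of
    incident edge weights; ``unweighted-rwr``: the propagation method run
    with every node and edge weight set to 1 (same beta).
    """
    pcfg = pcfg or PropagationConfig()
    out: dict[str, list[RankedGene]] = {}

    from .propagation import rank_candidates  # local to avoid circularity at import

    deg = {g: float(net.graph.degree(g)) for g in net.nodes}
    out["degree"] = rank_candidates(deg, net)

    wdeg = {
        g: float(sum(net.edge_weight(g, nb) for nb in sorted(net.graph.neighbors(g))))
        for g in net.nodes
    }
    out["weighted-degree"] = rank_candidates(wdeg, net)

    uni = assign_uniform_weights(net)
    Q = build_transition_matrix(uni)
    scores, _ = propagate(Q, initial_scores(uni), pcfg)
    out["unweighted-rwr"] = rank_candidates(scores, uni)
    return out
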