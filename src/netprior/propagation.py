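"""Disease-risk propagation: the transition matrix, the restart iteration,
and candidate ranking.

The model treats disease risk as a quantity diffusing over the weighted
network.  Column h of the transition matrix Q distributes gene h's risk
among its neighbors in proportion to edge weight:

    q(g|h) = w(h,g) / sum over l in neighbor(h) of w(h,l)

so every column of Q sums to 1 and Q is column-stochastic.  Risk scores
are iterated as

    D(i+1) = (1 - beta) * Q @ D(i) + beta * D(0)

with restart parameter beta in (0,1) (default 0.1) and the initial vector
D(0) proportional to the functional node weights, d_g(0) = w_g / sum_m w_m.
The iteration is a contraction with factor (1 - beta), so it converges
geometrically to the unique fixed point D* = beta (I - (1-beta) Q)^-1 D(0);
iteration stops once successive iterates differ by less than the tolerance
(default 1e-9, L1 norm).  Candidates are ranked by fixed-point score in
descending order, ties broken lexicographically on the gene symbol for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .network import WeightedNetwork

ISOLATED_POLICIES = ("self-loop", "error")
NORMS = ("l1", "linf")


@dataclass
class PropagationConfig:
    beta: float = 0.1
    tolerance: float = 1e-9
    max_iterations: int = 10000
    norm: str = "l1"

    def __post_init__(self) -> None:
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie strictly between 0 and 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be a positive integer")
        if self.norm not in NORMS:
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass
class TransitionMatrix:
    """Column-stochastic risk-transfer operator over a fixed node order."""

    matrix: sp.csc_matrix
    nodes: tuple[str, ...]

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray()


class RankedGene(NamedTuple):
    gene: str
    score: float
    rank: int
    is_seed: bool


class ConvergenceError(RuntimeError):
    """Raised when the propagation does not converge within the iteration
    cap; carries the last iterate and residual."""

    def __init__(self, message: str, last_iterate: np.ndarray, residual: float):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.residual = residual


def build_transition_matrix(
    net: WeightedNetwork, isolated_policy: str = "self-loop"
) -> TransitionMatrix:
    """Build Q with q(g|h) = w(h,g) / sum_l w(h,l) over the neighbors of h.

    A node with no neighbors (or zero total incident weight) has no
    well-defined column; under the default ``self-loop`` policy it keeps
    its own risk (q(h|h) = 1), under ``error`` it raises, naming the gene.
    """
    if isolated_policy not in ISOLATED_POLICIES:
        raise ValueError(f"unknown isolated-node policy {isolated_policy!r}")
    nodes = net.nodes
    index = {n: i for i, n in enumerate(nodes)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for h in nodes:
        # canonical neighbor order: summation must not depend on the
        # insertion order of the input edge list
        nbrs = sorted(net.graph.neighbors(h))
        total = sum(net.edge_weight(h, g) for g in nbrs)
        if not nbrs or total <= 0.0:
            if isolated_policy == "error":
                raise ValueError(
                    f"gene {h!r} has no positive-weight interaction; "
                    "cannot normalize its transition column"
                )
            rows.append(index[h])
            cols.append(index[h])
            vals.append(1.0)
            continue
        for g in nbrs:
            rows.append(index[g])
            cols.append(index[h])
            vals.append(net.edge_weight(h, g) / total)
    n = len(nodes)
    q = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(matrix=q, nodes=nodes)


def initial_scores(net: WeightedNetwork, seed_restricted: bool = False) -> np.ndarray:
    """Initial risk vector D(0): node weights normalized to sum to 1.

    Every network gene participates, seeds and candidates alike.  The
    ``seed_restricted`` variant (classic random-walk-with-restart restart
    vector, offered for comparison only) zeroes out non-seed genes before
    normalizing.
    """
    nodes = net.nodes
    w = np.array([net.node_weight(n) for n in nodes], dtype=float)
    if seed_restricted:
        seed_mask = np.array(
            [net.graph.nodes[n]["is_seed"] for n in nodes], dtype=bool
        )
        w = np.where(seed_mask, w, 0.0)
    total = w.sum()
    if total <= 0.0:
        raise ValueError("all node weights are zero; D(0) undefined")
    return w / total


def propagate(
    Q: TransitionMatrix | sp.spmatrix,
    d0: np.ndarray,
    cfg: Optional[PropagationConfig] = None,
    callback: Optional[Callable[[int, np.ndarray, float], None]] = None,
) -> tuple[np.ndarray, int]:
    """Iterate D(i+1) = (1-beta) Q D(i) + beta D(0) to convergence.

    Returns the first iterate whose distance from its predecessor falls
    below the tolerance, together with the iteration count.  ``callback``
    (if given) receives ``(iteration, iterate, residual)`` after each step.

    Raises
    ------
    ConvergenceError
        if the cap is hit; the exception carries the last iterate.
    """
    cfg = cfg or PropagationConfig()
    A = Q.matrix if isinstance(Q, TransitionMatrix) else Q
    ord_ = 1 if cfg.norm == "l1" else np.inf
    d0 = np.asarray(d0, dtype=float)
    # Iterate the increment delta(i+1) = (1-beta) Q delta(i) and accumulate
    # d(i+1) = d(i) + delta(i+1): algebraically identical to the plain
    # recurrence, but the residual ||delta|| is formed without the
    # catastrophic cancellation of subtracting two nearly equal iterates.
    damp = 1.0 - cfg.beta
    delta = damp * (A @ d0 - d0)
    d = d0 + delta
    for i in range(1, cfg.max_iterations + 1):
        residual = float(np.linalg.norm(delta, ord=ord_))
        if callback is not None:
            callback(i, d, residual)
        if residual < cfg.tolerance:
            return d, i
        delta = damp * (A @ delta)
        d = d + delta
    raise ConvergenceError(
        f"propagation did not converge in {cfg.max_iterations} iterations "
        f"(last residual {residual:.3e})",
        last_iterate=d,
        residual=residual,
    )


def fixed_point_scores(
    net: WeightedNetwork,
    cfg: Optional[PropagationConfig] = None,
    isolated_policy: str = "self-loop",
) -> tuple[np.ndarray, int]:
    """Convenience: build Q and D(0) from the network and propagate."""
    Q = build_transition_matrix(net, isolated_policy=isolated_policy)
    d0 = initial_scores(net)
    return propagate(Q, d0, cfg)


def rank_candidates(
    scores: np.ndarray | dict,
    net: WeightedNetwork,
    include_seeds: bool = False,
) -> list[RankedGene]:
    """Sort genes by risk score, descending; ties break lexicographically.

    With ``include_seeds=False`` seeds are removed *before* ranks are
    assigned, so candidate ranks run 1..#candidates.
    """
    nodes = net.nodes
    if isinstance(scores, dict):
        score_of = scores
    else:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(nodes),):
            raise ValueError("score vector does not cover all network nodes")
        score_of = dict(zip(nodes, scores))
    pool = nodes if include_seeds else net.candidates
    ordered = sorted(pool, key=lambda g: (-score_of[g], g))
    return [
        RankedGene(g, float(score_of[g]), rank, net.graph.nodes[g]["is_seed"])
        for rank, g in enumerate(ordered, start=1)
    ]


class BetaSweepRow(NamedTuple):
    beta: float
    metric: float
    is_best: bool


def beta_sweep(
    betas: Sequence[float], evaluator: Callable[[float], float]
) -> list[BetaSweepRow]:
    """Evaluate a metric (LOOCV AUC by default usage) at each beta.

    Returns one row per beta with the best-performing beta flagged;
    the first beta wins ties.
    """
    betas = list(betas)
    if not betas:
        raise ValueError("empty beta list")
    if any(not 0.0 < b < 1.0 for b in betas):
        raise ValueError("all betas must lie strictly between 0 and 1")
    metrics = [float(evaluator(b)) for b in betas]
    best = int(np.argmax(metrics))
    return [
        BetaSweepRow(beta=b, metric=m, is_best=(i == best))
        for i, (b, m) in enumerate(zip(betas, metrics))
    ]
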