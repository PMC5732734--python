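"""Transition matrix, restart iteration, ranking: exactness against
closed-form linear-algebra oracles and the documented contracts."""

from __future__ import annotations

import numpy as np
import pytest

from netprior.propagation import (
    ConvergenceError,
    PropagationConfig,
    beta_sweep,
    build_transition_matrix,
    initial_scores,
    propagate,
    rank_candidates,
)

from conftest import make_net, random_connected_network


def closed_form_fixed_point(Q, d0, beta):
    """Independent oracle: D* = beta (I - (1-beta) Q)^-1 D(0), dense solve."""
    A = Q.toarray()
    n = A.shape[0]
    return beta * np.linalg.solve(np.eye(n) - (1 - beta) * A, d0)


def neumann_series(Q, d0, beta, k_max=200):
    """Second oracle: truncated series sum_k beta (1-beta)^k Q^k D(0)."""
    A = Q.toarray()
    term = d0.copy()
    acc = beta * term
    for _ in range(k_max):
        term = (1 - beta) * (A @ term)
        acc += beta * term
    return acc


class TestTransitionMatrix:
    def test_triangle_uniform(self, triangle):
        Q = build_transition_matrix(triangle)
        dense = Q.toarray()
        assert np.allclose(dense[dense > 0], 0.5)
        assert np.allclose(Q.column_sums(), 1.0)

    def test_path_weighted_normalization(self):
        net = make_net(
            [("A", "B"), ("B", "C")],
            edge_weights={("A", "B"): 1.0, ("B", "C"): 3.0},
        )
        Q = build_transition_matrix(net)
        idx = {n: i for i, n in enumerate(Q.nodes)}
        col_b = Q.toarray()[:, idx["B"]]
        assert col_b[idx["A"]] == pytest.approx(1 / 4)
        assert col_b[idx["C"]] == pytest.approx(3 / 4)

    def test_isolated_node_error_policy(self):
        net = make_net([("A", "B")])
        net.graph.add_node("LONER", weight=1.0, is_seed=False)
        with pytest.raises(ValueError, match="LONER"):
            build_transition_matrix(net, isolated_policy="error")

    def test_isolated_node_self_loop_policy(self):
        net = make_net([("A", "B")])
        net.graph.add_node("LONER", weight=1.0, is_seed=False)
        Q = build_transition_matrix(net)
        idx = {n: i for i, n in enumerate(Q.nodes)}
        assert Q.toarray()[idx["LONER"], idx["LONER"]] == 1.0
        assert np.allclose(Q.column_sums(), 1.0)

    def test_zero_weight_column_follows_isolated_policy(self):
        net = make_net([("A", "B")], edge_weights={("A", "B"): 0.0})
        with pytest.raises(ValueError, match="A"):
            build_transition_matrix(net, isolated_policy="error")


class TestInitialScores:
    def test_weight_proportional(self):
        net = make_net([("A", "B"), ("B", "C")],
                       node_weights={"A": 2.0, "B": 1.0, "C": 1.0})
        d0 = initial_scores(net)
        assert dict(zip(net.nodes, d0)) == {"A": 0.5, "B": 0.25, "C": 0.25}

    def test_uniform_weights(self):
        net = make_net([("A", "B"), ("B", "C"), ("C", "D")])
        assert np.allclose(initial_scores(net), 1 / 4)

    def test_all_zero_weights_error(self):
        net = make_net([("A", "B")], node_weights={"A": 0.0, "B": 0.0})
        with pytest.raises(ValueError):
            initial_scores(net)

    def test_seed_restricted_variant(self):
        net = make_net([("A", "B"), ("B", "C")], seeds=("A",))
        d0 = initial_scores(net, seed_restricted=True)
        assert dict(zip(net.nodes, d0)) == {"A": 1.0, "B": 0.0, "C": 0.0}


class TestPropagate:
    def test_symmetric_pair_fixed_at_first_iteration(self):
        net = make_net([("A", "B")])
        Q = build_transition_matrix(net)
        d, iters = propagate(Q, initial_scores(net), PropagationConfig(beta=0.37))
        assert iters == 1
        assert np.allclose(d, 0.5)

    @pytest.mark.parametrize("beta", [0.1, 0.5, 0.9])
    def test_matches_closed_form_on_random_networks(self, beta):
        rng = np.random.default_rng(1234)
        for _ in range(10):
            net = random_connected_network(rng)
            Q = build_transition_matrix(net)
            d0 = initial_scores(net)
            d, _ = propagate(Q, d0, PropagationConfig(beta=beta))
            assert np.max(np.abs(d - closed_form_fixed_point(Q, d0, beta))) < 1e-8

    def test_matches_neumann_series(self):
        rng = np.random.default_rng(99)
        net = random_connected_network(rng)
        Q = build_transition_matrix(net)
        d0 = initial_scores(net)
        d, _ = propagate(Q, d0)
        assert np.max(np.abs(d - neumann_series(Q, d0, 0.1))) < 1e-6

    def test_restart_dominated_limit(self):
        rng = np.random.default_rng(7)
        net = random_connected_network(rng)
        Q = build_transition_matrix(net)
        d0 = initial_scores(net)
        d, _ = propagate(Q, d0, PropagationConfig(beta=0.999))
        assert np.max(np.abs(d - d0)) < 1e-2

    def test_mass_conserved_every_iterate(self):
        rng = np.random.default_rng(5)
        net = random_connected_network(rng)
        Q = build_transition_matrix(net)
        sums = []
        propagate(Q, initial_scores(net), callback=lambda i, d, r: sums.append(d.sum()))
        assert np.max(np.abs(np.array(sums) - 1.0)) < 1e-12 * len(sums)

    def test_residuals_bounded_by_contraction(self):
        rng = np.random.default_rng(6)
        net = random_connected_network(rng)
        Q = build_transition_matrix(net)
        residuals = []
        propagate(Q, initial_scores(net),
                  callback=lambda i, d, r: residuals.append(r))
        beta = 0.1
        for i in range(1, len(residuals) - 1):
            assert residuals[i + 1] <= residuals[i] * (1 - beta) + 1e-15

    def test_iteration_cap_raises_with_last_iterate(self):
        net = make_net([("A", "B"), ("B", "C")],
                       node_weights={"A": 1.0, "B": 0.2, "C": 0.1})
        Q = build_transition_matrix(net)
        with pytest.raises(ConvergenceError) as exc:
            propagate(Q, initial_scores(net), PropagationConfig(max_iterations=2))
        assert exc.value.last_iterate.shape == (3,)
        assert exc.value.residual > 0

    def test_deterministic_bit_identical(self):
        rng = np.random.default_rng(8)
        net = random_connected_network(rng)
        Q = build_transition_matrix(net)
        d0 = initial_scores(net)
        d1, i1 = propagate(Q, d0)
        d2, i2 = propagate(Q, d0)
        assert i1 == i2 and np.array_equal(d1, d2)


class TestConfigValidation:
    @pytest.mark.parametrize("beta", [0.0, 1.0, -0.5, 2.0])
    def test_beta_open_interval(self, beta):
        with pytest.raises(ValueError):
            PropagationConfig(beta=beta)

    def test_tolerance_positive(self):
        with pytest.raises(ValueError):
            PropagationConfig(tolerance=0.0)


class TestRanking:
    def test_candidates_only_excludes_seeds_before_ranking(self):
        net = make_net([("A", "B"), ("A", "C")], seeds=("A",))
        ranking = rank_candidates({"A": 0.5, "B": 0.3, "C": 0.2}, net)
        assert [(r.gene, r.rank) for r in ranking] == [("B", 1), ("C", 2)]

    def test_include_seeds(self):
        net = make_net([("A", "B"), ("A", "C")], seeds=("A",))
        ranking = rank_candidates({"A": 0.5, "B": 0.3, "C": 0.2}, net,
                                  include_seeds=True)
        assert [(r.gene, r.rank) for r in ranking] == [("A", 1), ("B", 2), ("C", 3)]

    def test_tie_broken_lexicographically(self):
        net = make_net([("A", "B"), ("A", "C")], seeds=("A",))
        ranking = rank_candidates({"A": 0.5, "C": 0.3, "B": 0.3}, net)
        assert [r.gene for r in ranking] == ["B", "C"]

    def test_scores_must_cover_all_nodes(self):
        net = make_net([("A", "B")])
        with pytest.raises(ValueError):
            rank_candidates(np.array([0.5]), net)


class TestBetaSweep:
    def test_single_beta_matches_direct_call(self):
        calls = []

        def ev(beta):
            calls.append(beta)
            return beta * 2

        rows = beta_sweep([0.3], ev)
        assert rows == [(0.3, 0.6, True)]
        assert calls == [0.3]

    def test_nine_betas_flag_argmax(self):
        rows = beta_sweep([b / 10 for b in range(1, 10)], lambda b: -(b - 0.4) ** 2)
        assert len(rows) == 9
        assert [r.beta for r in rows if r.is_best] == [0.4]

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            beta_sweep([], lambda b: b)

    def test_out_of_range_beta_errors(self):
        with pytest.raises(ValueError):
            beta_sweep([0.0, 0.5], lambda b: b)
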