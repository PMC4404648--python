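import itertools
import random

import numpy as np
import pytest

from hsmnet import (
    AnnealingConfig,
    DirectedNetwork,
    HierarchyScoreMaximizer,
    LevelAssignment,
    ProbabilityMatrix,
    anneal_once,
    assess_significance,
    classify_edges,
    discretize,
    generate_erdos_renyi,
    generate_perfect_hierarchy,
    hierarchy_score,
    run_hsm,
    select_levels,
)
from conftest import random_digraph


def exhaustive_best_hs(net: DirectedNetwork, n_levels: int):
    """Enumeration oracle: max HS over all n_levels**n assignments."""
    best = None
    for combo in itertools.product(range(1, n_levels + 1),
                                   repeat=net.n_nodes):
        asg = LevelAssignment(dict(zip(net.nodes, combo)), n_levels)
        hs = hierarchy_score(classify_edges(net, asg))
        if best is None or hs > best:
            best = hs
    return best


class TestAnnealOnce:
    def test_zero_steps_returns_initial_assignment(self, toy_net):
        cfg = AnnealingConfig(n_levels=3, n_steps=0, n_restarts=1)
        asg, hs = anneal_once(toy_net, cfg, run_seed=5)
        rng = random.Random(5 * 1_000_003)  # restart 0 sub-seed
        expected = [rng.randrange(3) + 1 for _ in toy_net.nodes]
        assert [asg.levels[n] for n in toy_net.nodes] == expected
        assert hs == hierarchy_score(classify_edges(toy_net, asg))

    def test_recovers_perfect_hierarchy(self, military):
        cfg = AnnealingConfig(n_levels=5)
        asg, hs = anneal_once(military.network, cfg, run_seed=0)
        assert not hs.is_finite  # HS = +inf: all edges downward
        assert asg.levels == military.truth.levels

    def test_toy_network_reaches_exhaustive_optimum(self, toy_net):
        oracle = exhaustive_best_hs(toy_net, 3)
        cfg = AnnealingConfig(n_levels=3)
        _, hs = anneal_once(toy_net, cfg, run_seed=1)
        assert hs == oracle

    def test_l_below_two_rejected(self, toy_net):
        with pytest.raises(ValueError):
            AnnealingConfig(n_levels=1)

    def test_warns_when_levels_exceed_nodes(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "c")])
        with pytest.warns(UserWarning, match="exceeds node count"):
            anneal_once(net, AnnealingConfig(n_levels=4, n_steps=10,
                                             n_restarts=1), run_seed=0)

    def test_warm_start_accepted(self, military):
        cfg = AnnealingConfig(n_levels=5, n_steps=0, n_restarts=1)
        asg, hs = anneal_once(military.network, cfg, run_seed=0,
                              initial=military.truth)
        assert asg.levels == military.truth.levels
        assert not hs.is_finite


class TestRunHsm:
    def test_perfect_recovery_one_hot_matrix(self, military):
        result = run_hsm(military.network,
                         AnnealingConfig(n_levels=5, n_runs=25, seed=2))
        pm = result.probability_matrix
        for node in military.network.nodes:
            assert pm.row(node)[military.truth.levels[node] - 1] == 1.0
        assert not result.hs.is_finite  # +inf
        assert result.best_assignment.levels == military.truth.levels

    def test_single_run_matrix_is_one_hot(self, toy_net):
        result = run_hsm(toy_net, AnnealingConfig(n_levels=3, n_runs=1, seed=4))
        assert np.all(np.isin(result.probability_matrix.probs, (0.0, 1.0)))
        assert float(result.phs) == pytest.approx(float(result.hs))

    def test_best_hs_is_max_of_per_run_scores(self, toy_net):
        result = run_hsm(toy_net, AnnealingConfig(n_levels=3, n_runs=8, seed=6))
        assert result.hs == max(result.per_run_scores)

    def test_reproducible_with_same_seed(self, toy_net):
        cfg = AnnealingConfig(n_levels=3, n_runs=6, seed=9)
        r1, r2 = run_hsm(toy_net, cfg), run_hsm(toy_net, cfg)
        assert r1.best_assignment.levels == r2.best_assignment.levels
        np.testing.assert_array_equal(r1.probability_matrix.probs,
                                      r2.probability_matrix.probs)
        assert [float(s) for s in r1.per_run_scores] == \
            [float(s) for s in r2.per_run_scores]

    def test_interchangeable_nodes_get_matching_rows(self):
        # b1 and b2 have identical in/out neighborhoods; by symmetry their
        # assignment frequencies agree up to binomial noise
        net = DirectedNetwork.from_edges(
            [("t", "m"), ("m", "b1"), ("m", "b2"), ("b1", "x"), ("b2", "x")])
        result = run_hsm(net, AnnealingConfig(n_levels=3, n_runs=400, seed=13))
        pm = result.probability_matrix
        r1, r2 = pm.row("b1"), pm.row("b2")
        # 3 sigma of a binomial proportion at k = 400
        assert np.all(np.abs(r1 - r2) < 3 * np.sqrt(0.25 / 400) + 1e-9)

    def test_rows_sum_exactly_to_one(self, toy_net):
        result = run_hsm(toy_net, AnnealingConfig(n_levels=3, n_runs=7, seed=1))
        assert np.all(result.probability_matrix.probs.sum(axis=1) == 1.0)


class TestDiscretize:
    def test_argmax_row(self):
        pm = ProbabilityMatrix(["a"], np.array([[0.1, 0.2, 0.7]]), 3, 0)
        asg, tied = discretize(pm)
        assert asg.levels["a"] == 3 and tied == []

    def test_one_hot_row(self):
        pm = ProbabilityMatrix(["a"], np.array([[0.0, 1.0]]), 2, 0)
        asg, _ = discretize(pm)
        assert asg.levels["a"] == 2

    def test_tie_goes_to_lower_level_and_is_flagged(self):
        pm = ProbabilityMatrix(["a"], np.array([[0.5, 0.5]]), 2, 0)
        asg, tied = discretize(pm)
        assert asg.levels["a"] == 1 and tied == ["a"]


class TestOracleEquivalence:
    def test_small_random_digraphs_reach_enumeration_maximum(self):
        rng = random.Random(17)
        for _ in range(12):
            net = random_digraph(rng, rng.randint(4, 7), p_edge=0.3,
                                 self_loops=True)
            oracle = exhaustive_best_hs(net, 3)
            result = run_hsm(net, AnnealingConfig(n_levels=3, n_runs=5,
                                                  seed=rng.randrange(1000)))
            assert result.hs == oracle


class TestSelectLevels:
    def test_bipartite_saturates_at_two(self):
        ph = generate_perfect_hierarchy([3, 2], branching="layered_random",
                                        seed=5)
        with pytest.warns(UserWarning):  # L=4 exceeds the tiny diameter
            chosen, per_L = select_levels(
                ph.network, [2, 3, 4],
                AnnealingConfig(n_levels=2, n_runs=8, seed=7))
        assert chosen == 2
        assert not per_L[2]["chs"].is_finite

    def test_er_network_picks_smallest_level_count(self):
        net = generate_erdos_renyi(30, 200, seed=31)
        chosen, per_L = select_levels(
            net, [2, 3], AnnealingConfig(n_levels=2, n_runs=4, seed=1),
            saturation_tol=0.5)
        assert chosen == 2

    def test_empty_range_rejected(self, toy_net):
        with pytest.raises(ValueError):
            select_levels(toy_net, [], AnnealingConfig(n_levels=2))


class TestSignificance:
    def test_perfect_hierarchy_beats_dense_nulls(self):
        # dense planted hierarchy: every ER null of equal size contains
        # cycles, so no null reaches an infinite HS
        ph = generate_perfect_hierarchy([16, 8, 4, 2, 1],
                                        branching="layered_random", seed=3,
                                        extra_edge_fraction=4.0)
        cfg = AnnealingConfig(n_levels=5, n_runs=2, n_restarts=1,
                              n_steps=8000, seed=5)
        report = assess_significance(ph.network, cfg, n_null=30, L_range=[5])
        assert report.per_level[5]["empirical_p"] == 0.0
        assert report.adjusted_p == 0.0

    def test_z_zero_gives_half_normal_p(self):
        # degenerate check through the report arithmetic
        from scipy import stats

        assert stats.norm.sf(0.0) == 0.5

    def test_er_vs_er_is_not_significant(self):
        net = generate_erdos_renyi(20, 60, seed=8)
        cfg = AnnealingConfig(n_levels=3, n_runs=2, n_restarts=1,
                              n_steps=4000, seed=21)
        report = assess_significance(net, cfg, n_null=40, L_range=[3])
        assert report.per_level[3]["empirical_p"] > 0.05

    def test_bonferroni_adjustment(self):
        ph = generate_perfect_hierarchy([4, 2, 1], seed=2)
        cfg = AnnealingConfig(n_levels=2, n_runs=2, n_restarts=1,
                              n_steps=2000, seed=3)
        report = assess_significance(ph.network, cfg, n_null=5,
                                     L_range=[2, 3])
        assert report.adjusted_p == min(1.0, report.min_p * 2)


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = HierarchyScoreMaximizer(n_levels=4, n_runs=7, random_state=3)
        params = est.get_params()
        assert params["n_levels"] == 4 and params["n_runs"] == 7
        est.set_params(n_levels=2)
        assert est.n_levels == 2

    def test_fit_predict_on_adjacency_matrix(self, military):
        idx = military.network.node_index()
        n = military.network.n_nodes
        adj = np.zeros((n, n))
        for u, v in military.network.edges:
            adj[idx[u], idx[v]] = 1
        labels = HierarchyScoreMaximizer(
            n_levels=5, n_runs=10, random_state=0).fit_predict(adj)
        truth = np.array([military.truth.levels[n_]
                          for n_ in military.network.nodes])
        np.testing.assert_array_equal(labels, truth)

    def test_fit_accepts_networkx(self, toy_net):
        est = HierarchyScoreMaximizer(n_levels=3, n_runs=3, random_state=0)
        est.fit(toy_net.to_networkx())
        assert list(est.nodes_) == list(toy_net.nodes)
        assert est.labels_.shape == (toy_net.n_nodes,)
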