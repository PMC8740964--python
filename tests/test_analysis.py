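"""Path probabilities, qualifying-path census, timeseries similarity."""

import itertools

import networkx as nx
import numpy as np
import pytest

from podsim import (
    BeliefSpace,
    GraphSpec,
    Institution,
    PathCensusSpec,
    SocialGraph,
    avg_pearson,
    believing_neighbor_set,
    beta_probability,
    chi2_timeseries,
    path_census,
    path_probability,
    preset,
    qualifying_path_exists,
    summarize_homophily,
    wire_subscribers,
)


class TestPathProbability:
    def test_empty_path_is_certain(self, dcc):
        assert path_probability(dcc, [], 6) == 1.0

    def test_two_near_nodes(self, dcc):
        assert path_probability(dcc, [5, 5], 6) == pytest.approx(0.982**2, abs=1e-3)

    def test_distant_node_collapses_chain(self, dcc):
        # one distance-3 node caps the whole product at ~0.018
        assert path_probability(dcc, [6, 6, 3, 6], 6) <= 0.018 + 1e-9

    def test_equals_product_of_pairwise_betas(self, dcc, rng):
        for _ in range(20):
            beliefs = rng.integers(0, 7, size=rng.integers(1, 6))
            expected = np.prod([beta_probability(dcc, int(b), 6) for b in beliefs])
            assert path_probability(dcc, beliefs, 6) == pytest.approx(expected, rel=1e-12)


def brute_force_best_path(sg, inst, target, message_level, spec):
    """Exhaustive max-product path probability to each neighbor of target."""
    g = sg.g.copy()
    g.remove_node(target)
    beliefs = sg.beliefs
    best = {}
    for v in sg.g.neighbors(target):
        best_p = 0.0
        for s in inst.subscribers:
            if s == target or s not in g:
                continue
            for path in nx.all_simple_paths(g, s, v):
                p = np.prod([beta_probability(spec, int(beliefs[u]), message_level) for u in path])
                best_p = max(best_p, p)
            if s == v:  # zero-length path: the neighbor is itself a subscriber
                best_p = max(best_p, beta_probability(spec, int(beliefs[v]), message_level))
        best[v] = best_p
    return best


class TestBelievingNeighborSet:
    def test_direct_subscriber_neighbor_included(self, fig2_toy, dcc):
        sg, inst = fig2_toy
        # node 3 (belief 5) neighbors subscribers 0 and 7; one hop through a
        # subscriber carries ~0.9997 >= 0.5
        out = believing_neighbor_set(sg, inst, target=3, message_level=6, delta=0.5, spec=dcc)
        assert 0 in out

    def test_delta_zero_empty_under_sigmoid(self, fig2_toy, dcc):
        sg, inst = fig2_toy
        # no sigmoid path has probability exactly 1
        assert believing_neighbor_set(sg, inst, 3, 6, delta=0.0, spec=dcc) == set()

    def test_matches_exhaustive_oracle_on_fixture(self, fig2_toy, dcc):
        sg, inst = fig2_toy
        for target in range(sg.n_agents):
            oracle = brute_force_best_path(sg, inst, target, 6, dcc)
            for delta in (0.1, 0.5, 0.9):
                expected = {v for v, p in oracle.items() if p >= 1 - delta}
                got = believing_neighbor_set(sg, inst, target, 6, delta, dcc)
                assert got == expected, (target, delta)

    def test_matches_oracle_on_random_small_graphs(self, dcc):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = nx.gnp_random_graph(8, 0.4, seed=seed)
            sg = SocialGraph(g)
            sg.set_beliefs(rng.integers(0, 7, 8))
            inst = wire_subscribers(sg, Institution(id="i1", belief=6), epsilon=1)
            for target in range(8):
                oracle = brute_force_best_path(sg, inst, target, 6, dcc)
                got = believing_neighbor_set(sg, inst, target, 6, 0.5, dcc)
                assert got == {v for v, p in oracle.items() if p >= 0.5}


def brute_force_qualifying_path(sg, inst, target, message_level, tau):
    """Enumerate simple paths subscriber -> neighbor-of-target; all nodes in tau."""
    beliefs = sg.beliefs
    g = sg.g.copy()
    g.remove_node(target)
    ok = lambda u: abs(int(beliefs[u]) - message_level) <= tau
    for v in sg.g.neighbors(target):
        for s in inst.subscribers:
            if s == target or not ok(s):
                continue
            if s == v and ok(v):
                return True
            for path in nx.all_simple_paths(g, s, v):
                if all(ok(u) for u in path):
                    return True
    return False


class TestQualifyingPath:
    def test_line_graph_tau_boundary(self):
        """institution -> a(d=1) -> b(d=2) -> target: blocked at tau=1, open at tau=2."""
        g = nx.path_graph(4)  # 0-1-2-3
        sg = SocialGraph(g)
        sg.set_beliefs([6, 5, 4, 0])  # distances to message 6: 0,1,2,6
        inst = wire_subscribers(sg, Institution(id="i1", belief=6), epsilon=0)
        assert not qualifying_path_exists(sg, inst, target=3, message_level=6, tau=1)
        assert qualifying_path_exists(sg, inst, target=3, message_level=6, tau=2)

    def test_no_agent_within_tau_is_false(self):
        sg = SocialGraph(nx.complete_graph(5))
        sg.set_beliefs([0] * 5)
        inst = wire_subscribers(sg, Institution(id="i1", belief=6), epsilon=6)
        assert not qualifying_path_exists(sg, inst, target=0, message_level=6, tau=1)

    def test_matches_exhaustive_enumeration(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            g = nx.gnp_random_graph(9, 0.3, seed=seed + 100)
            sg = SocialGraph(g)
            sg.set_beliefs(rng.integers(0, 7, 9))
            inst = wire_subscribers(sg, Institution(id="i1", belief=6), epsilon=1)
            for target, tau in itertools.product(range(9), (0, 1, 2, 3)):
                assert qualifying_path_exists(sg, inst, target, 6, tau) == \
                    brute_force_qualifying_path(sg, inst, target, 6, tau), (seed, target, tau)


class TestPathCensus:
    def test_monotone_in_tau(self):
        """Loosening the belief bound can only admit more graphs."""
        props = []
        for tau in (0, 1, 2):
            spec = PathCensusSpec(
                tau=tau, target_level=0, n_graphs=25, n_agents=80,
                graph_spec=GraphSpec(family="ER", er_rho=0.04),
            )
            props.append(path_census(spec, np.random.default_rng(3)))
        assert props[0] <= props[1] <= props[2]

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            PathCensusSpec(tau=9, target_level=0)


class TestAvgPearson:
    def make_ts(self, series_by_level):
        arr = np.array(series_by_level).T
        return arr

    def test_identical_nonconstant_is_one(self):
        ts = self.make_ts([[0.1, 0.2, 0.3], [0.9, 0.8, 0.7]])
        assert avg_pearson(ts, ts) == pytest.approx(1.0)

    def test_all_constant_is_undefined(self):
        ts = self.make_ts([[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]])
        assert avg_pearson(ts, ts) is None

    def test_constant_level_in_either_input_excluded(self):
        a = self.make_ts([[0.1, 0.2, 0.3], [0.2, 0.2, 0.2]])
        b = self.make_ts([[0.1, 0.25, 0.3], [0.9, 0.1, 0.4]])
        # only level 0 counts; level 1 is constant in a
        r = avg_pearson(a, b)
        assert r == pytest.approx(np.corrcoef(a[:, 0], b[:, 0])[0, 1])

    def test_symmetric_and_affine_invariant(self, rng):
        a = rng.random((20, 7))
        b = rng.random((20, 7))
        assert avg_pearson(a, b) == pytest.approx(avg_pearson(b, a))
        assert avg_pearson(2.0 * a + 0.3, 2.0 * b + 0.3) == pytest.approx(avg_pearson(a, b))

    def test_mismatched_horizons_rejected(self, rng):
        with pytest.raises(ValueError):
            avg_pearson(rng.random((10, 7)), rng.random((11, 7)))


class TestChi2Timeseries:
    def test_identical_tables_never_reject(self, rng):
        counts = rng.integers(10, 100, size=(20, 7))
        assert chi2_timeseries(counts, counts) == 1.0

    def test_maximally_different_always_rejects(self):
        a = np.zeros((15, 7), dtype=int)
        b = np.zeros((15, 7), dtype=int)
        a[:, 0] = 500
        b[:, 6] = 500
        assert chi2_timeseries(a, b) == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            chi2_timeseries(np.zeros((5, 7)), np.zeros((6, 7)))


class TestSummarizeHomophily:
    def test_needs_at_least_two_graphs(self, rng):
        with pytest.raises(ValueError):
            summarize_homophily(GraphSpec(family="ER"), 1, rng)

    def test_er_small_ensemble_near_expected(self):
        mean, var = summarize_homophily(
            GraphSpec(family="ER", er_rho=0.05), 4, np.random.default_rng(0), n_agents=300
        )
        assert mean == pytest.approx(112 / 49, abs=0.1)
        assert var >= 0.0
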