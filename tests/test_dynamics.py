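"""Threshold cascade: seeding, single steps, full runs, oracle equivalence."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from innodiff.cognition import CognitionSpec, sample_cognition
from innodiff.dynamics import PopulationState, run_cascade, seed_adopters, step
from innodiff.network import ObservationNetwork, generate_ba
from tests.conftest import brute_force_fixed_point


def _net(graph):
    return ObservationNetwork(graph=graph)


def _state(bits, t=0):
    return PopulationState(w=np.array(bits, dtype=np.int8), t=t)


class TestSeedAdopters:
    def test_degenerate_probabilities(self, rng):
        assert seed_adopters(20, 0.0, rng).w.sum() == 0
        assert seed_adopters(20, 1.0, rng).w.sum() == 20

    def test_seed_fraction_near_probability(self, rng):
        state = seed_adopters(10000, 0.3, rng)
        assert abs(state.w.mean() - 0.3) < 0.02
        assert state.t == 0

    @pytest.mark.parametrize("p", [-0.1, 1.1])
    def test_rejects_bad_probability(self, p, rng):
        with pytest.raises(ValueError, match="p"):
            seed_adopters(10, p, rng)


class TestStep:
    def test_adopts_when_perceived_value_clears_threshold(self):
        # path 0-1-2, middle node sees q = 0.5
        net = _net(nx.path_graph(3))
        out = step(net, _state([1, 0, 0]), [0.1, 0.9, 0.1])
        assert list(out.w) == [1, 1, 0]
        assert out.t == 1

    def test_holds_when_perceived_value_below_threshold(self):
        net = _net(nx.path_graph(3))
        out = step(net, _state([1, 0, 0]), [0.1, 0.1, 0.1])
        assert list(out.w) == [1, 0, 0]

    def test_boundary_equality_adopts(self):
        # non-strict rule: mu = 1 - q exactly triggers adoption
        net = _net(nx.path_graph(3))
        out = step(net, _state([1, 0, 0]), [0.1, 0.5, 0.1])
        assert list(out.w) == [1, 1, 0]

    def test_uses_input_state_only(self):
        # synchronous: node 2 must not see node 1's same-step adoption
        net = _net(nx.path_graph(3))
        out = step(net, _state([1, 0, 0]), [0.9, 0.9, 0.9])
        assert list(out.w) == [1, 1, 0]

    def test_adopters_never_revert(self):
        net = _net(nx.path_graph(3))
        out = step(net, _state([1, 1, 1]), [0.01, 0.01, 0.01])
        assert list(out.w) == [1, 1, 1]

    def test_size_mismatch_raises(self):
        net = _net(nx.path_graph(3))
        with pytest.raises(ValueError, match="inconsistent"):
            step(net, _state([1, 0]), [0.5, 0.5, 0.5])


class TestRunCascade:
    def test_complete_graph_saturates_in_one_step(self):
        """K3, one seed, others with mu = 0.6: each sees q = 1/2 and
        1 - q = 0.5 <= 0.6, so both adopt at t = 1."""
        traj = run_cascade(_net(nx.complete_graph(3)), [0.6, 0.6, 0.6],
                           _state([1, 0, 0]), t_total=10)
        assert traj.acceptance_series[0] == pytest.approx(1 / 3)
        assert np.all(traj.acceptance_series[1:] == 1.0)
        assert traj.stabilization_time == 1

    def test_no_seeds_nothing_happens(self, rng):
        net = generate_ba(20, 2, rng)
        traj = run_cascade(net, np.full(20, 0.99), _state([0] * 20), t_total=10)
        assert np.all(traj.acceptance_series == 0.0)
        assert traj.stabilization_time == 0

    def test_all_seeded_stays_full(self, rng):
        net = generate_ba(20, 2, rng)
        traj = run_cascade(net, np.full(20, 0.01), _state([1] * 20), t_total=10)
        assert np.all(traj.acceptance_series == 1.0)
        assert traj.stabilization_time == 0

    def test_series_has_horizon_plus_one_entries_and_constant_tail(self, rng):
        net = generate_ba(50, 2, rng)
        mu = sample_cognition(50, CognitionSpec(0.5, 0.9), rng)
        init = seed_adopters(50, 0.3, rng)
        traj = run_cascade(net, mu, init, t_total=100)
        assert traj.acceptance_series.shape == (101,)
        # fixed point within n steps: constant on [n, t_total]
        assert np.all(traj.acceptance_series[50:] == traj.acceptance_series[50])
        assert traj.stabilization_time <= 50

    def test_snapshots_record_every_step(self, rng):
        net = generate_ba(10, 2, rng)
        traj = run_cascade(net, np.full(10, 0.5), _state([1] + [0] * 9),
                           t_total=7, record_states=True)
        assert len(traj.state_snapshots) == 8
        assert [s.t for s in traj.state_snapshots] == list(range(8))

    def test_rejects_zero_horizon(self, rng):
        net = generate_ba(5, 2, rng)
        with pytest.raises(ValueError, match="t_total"):
            run_cascade(net, np.full(5, 0.5), _state([1, 0, 0, 0, 0]), t_total=0)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), sigma=st.sampled_from([0.3, 0.5, 0.7]),
       mu0=st.sampled_from([0.1, 0.5, 0.9]))
def test_cascade_is_monotone_and_fixes_within_n_steps(seed, sigma, mu0):
    rng = np.random.default_rng(seed)
    net = generate_ba(40, 2, rng)
    mu = sample_cognition(40, CognitionSpec(sigma, mu0), rng)
    init = seed_adopters(40, 0.3, rng)
    traj = run_cascade(net, mu, init, t_total=60)
    assert np.all(np.diff(traj.acceptance_series) >= 0)
    assert np.all(traj.acceptance_series[40:] == traj.acceptance_series[40])


def test_step_is_invariant_under_node_relabeling(rng):
    """Synchronous updates cannot depend on evaluation order, so a relabeled
    graph with permuted inputs yields the permuted output."""
    net = generate_ba(15, 2, rng)
    mu = sample_cognition(15, CognitionSpec(0.5, 0.7), rng).values
    w = seed_adopters(15, 0.3, rng).w
    out = step(net, _state(w), mu).w
    perm = np.random.default_rng(9).permutation(15)
    relabeled = ObservationNetwork(
        graph=nx.relabel_nodes(net.graph, {i: int(perm[i]) for i in range(15)})
    )
    mu_p = np.empty(15)
    mu_p[perm] = mu
    w_p = np.empty(15, dtype=np.int8)
    w_p[perm] = w
    out_p = step(relabeled, _state(w_p), mu_p).w
    assert np.array_equal(out_p[perm], out)


def test_raising_one_cognition_never_shrinks_final_adopters():
    """Threshold monotonicity on toy graphs up to 8 nodes."""
    rng = np.random.default_rng(1234)
    for graph in [nx.cycle_graph(6), nx.star_graph(7), nx.path_graph(8),
                  nx.complete_graph(5)]:
        n = graph.number_of_nodes()
        net = _net(graph)
        for _ in range(20):
            mu = rng.uniform(0.05, 1.0, n)
            w0 = (rng.random(n) < 0.3).astype(np.int8)
            base = run_cascade(net, mu, _state(w0), t_total=n + 2).final_state.w
            i = int(rng.integers(n))
            mu_up = mu.copy()
            mu_up[i] = min(1.0, mu_up[i] + rng.uniform(0, 1 - mu_up[i] + 1e-12))
            raised = run_cascade(net, mu_up, _state(w0), t_total=n + 2).final_state.w
            assert np.all(raised >= base)


def test_cascade_matches_brute_force_oracle_on_all_small_graphs():
    """Exact equivalence with an independent fixed-point oracle on every
    graph with at most 5 nodes, every seed pattern and a cognition grid."""
    atlas = [g for g in nx.graph_atlas_g()[1:] if g.number_of_nodes() <= 5]
    mu_grid = [0.25, 0.5, 0.75, 1.0]
    het = np.random.default_rng(77)
    for graph in atlas:
        n = graph.number_of_nodes()
        net = _net(graph)
        adj = {i: set(graph.adj[i]) for i in range(n)}
        mu_cases = [np.full(n, m) for m in mu_grid]
        mu_cases += [het.uniform(0.05, 1.0, n) for _ in range(2)]
        for bits in itertools.product((0, 1), repeat=n):
            for mu in mu_cases:
                traj = run_cascade(net, mu, _state(bits), t_total=n + 1)
                expected = brute_force_fixed_point(adj, bits, mu)
                assert list(traj.final_state.w) == expected
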