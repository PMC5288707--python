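import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

from tdcnet import (
    PropagatorState,
    SpreadingParams,
    TemporalNetwork,
    ever_infected_probabilities,
    infection_recursion,
    normalize_scores,
    shifted_scores,
    step_matrix,
    tdc_scores,
)
from conftest import make_network, random_er_network
import oracles


class TestStepMatrix:
    def test_zero_dynamics_is_identity(self, chain_forward):
        p = SpreadingParams(beta=0.0, mu=0.0, horizon=1)
        h = step_matrix(chain_forward, 1, p).toarray()
        assert np.array_equal(h, np.eye(3))

    def test_direct_formula(self, chain_forward):
        p = SpreadingParams(beta=0.1, mu=0.1, horizon=1)
        h = step_matrix(chain_forward, 1, p).toarray()
        expected = np.array([[0.9, 0.1, 0.0], [0.1, 0.9, 0.0], [0.0, 0.0, 0.9]])
        assert np.allclose(h, expected, atol=1e-15)
        assert np.allclose(h, h.T)

    def test_beta_mu_one_gives_adjacency(self, chain_forward):
        p = SpreadingParams(beta=1.0, mu=1.0, horizon=1)
        h = step_matrix(chain_forward, 2, p).toarray()
        assert np.array_equal(h, chain_forward.snapshots[1].toarray())


class TestInfectionRecursion:
    def test_forward_chain_hand_values(self, chain_forward, chain_params):
        pv = infection_recursion(chain_forward, "A", chain_params)
        assert np.allclose(pv.newly[0], [0.0, 0.1, 0.0], atol=1e-15)
        assert np.allclose(pv.newly[1], [0.0, 0.0, 0.01], atol=1e-15)
        assert np.allclose(pv.final, [0.0, 0.1, 0.01], atol=1e-15)

    def test_reversed_chain_shows_time_order_sensitivity(
        self, chain_reversed, chain_params
    ):
        pv = infection_recursion(chain_reversed, "A", chain_params)
        assert np.allclose(pv.newly[0], [0.0, 0.0, 0.0], atol=1e-15)
        # y(1)_A = 1 - mu, so P(2)_B = beta * 0.9 = 0.09
        assert np.allclose(pv.newly[1], [0.0, 0.09, 0.0], atol=1e-15)

    def test_beta_zero_is_all_zero(self, chain_forward):
        p = SpreadingParams(beta=0.0, mu=0.3, horizon=4)
        pv = infection_recursion(chain_forward, "B", p)
        assert np.all(pv.newly == 0.0)

    def test_unknown_seed_errors(self, chain_forward, chain_params):
        with pytest.raises(KeyError, match="unknown seed"):
            infection_recursion(chain_forward, "Z", chain_params)

    def test_cumulative_is_prefix_sum_and_nonnegative(self, chain_forward):
        p = SpreadingParams(beta=0.3, mu=0.2, horizon=6)
        pv = infection_recursion(chain_forward, "A", p)
        assert np.allclose(pv.cumulative[-1], pv.final)
        assert np.all(pv.newly >= 0.0)

    def test_matches_dense_closed_form_on_random_networks(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_er_network(rng, n_max=12, l_max=6)
            beta = float(rng.uniform(0, 1))
            mu = float(rng.uniform(0, 1))
            horizon = int(rng.integers(1, 2 * net.n_snapshots))
            p = SpreadingParams(beta=beta, mu=mu, horizon=horizon)
            seed = net.nodes[int(rng.integers(net.n_nodes))]
            pv = infection_recursion(net, seed, p)
            expected = oracles.closed_form_newly_infected(
                oracles.dense_snapshots(net),
                net.node_index[seed],
                beta,
                mu,
                horizon,
            )
            assert np.allclose(pv.newly, expected, rtol=1e-12, atol=1e-14)


class TestPropagatorState:
    def test_left_product_invariants(self, chain_forward, chain_params):
        state = PropagatorState.build(chain_forward, chain_params)
        assert np.array_equal(state.left_products[0], np.eye(3))
        for r in range(1, len(state.step_matrices) + 1):
            assert np.allclose(
                state.left_products[r],
                state.step_matrices[r - 1] @ state.left_products[r - 1],
            )
            assert np.allclose(
                state.step_matrices[r - 1], state.step_matrices[r - 1].T
            )


class TestTdcScores:
    def test_forward_chain_hand_values(self, chain_forward, chain_params):
        s = tdc_scores(chain_forward, chain_params)
        assert s.scores["A"] == pytest.approx(0.11, abs=1e-12)
        assert s.scores["B"] == pytest.approx(0.19, abs=1e-12)
        assert s.scores["C"] == pytest.approx(0.09, abs=1e-12)
        ranked = sorted(s.scores, key=s.scores.get, reverse=True)
        assert ranked == ["B", "A", "C"]

    def test_routes_agree_on_random_networks(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            net = random_er_network(rng, n_max=30, l_max=10)
            p = SpreadingParams(
                beta=float(rng.uniform(0, 1)),
                mu=float(rng.uniform(0, 1)),
                horizon=int(rng.integers(1, 15)),
            )
            one = tdc_scores(net, p).vector(net.nodes)
            per = tdc_scores(net, p, method="perseed").vector(net.nodes)
            assert np.allclose(one, per, rtol=1e-10)

    def test_static_reduction_matches_independent_dsc(self):
        rng = np.random.default_rng(23)
        for _ in range(8):
            n = int(rng.integers(4, 15))
            a = np.triu((rng.random((n, n)) < 0.4).astype(float), 1)
            a = a + a.T
            L = int(rng.integers(2, 6))
            net = TemporalNetwork(list(range(n)), [sparse.csr_matrix(a)] * L)
            horizon = int(rng.integers(1, 9))
            beta, mu = float(rng.uniform(0, 0.5)), float(rng.uniform(0, 1))
            p = SpreadingParams(beta=beta, mu=mu, horizon=horizon)
            got = tdc_scores(net, p).vector(net.nodes)
            expected = oracles.liu_static_dsc(a, beta, mu, horizon)
            assert np.allclose(got, expected, rtol=1e-10)

    def test_isolated_node_scores_zero(self):
        net = TemporalNetwork(["X"], [sparse.csr_matrix((1, 1))])
        p = SpreadingParams(beta=0.7, mu=0.2, horizon=5)
        assert tdc_scores(net, p).scores["X"] == 0.0

    def test_monotone_in_horizon(self, chain_forward):
        prev = None
        for t in range(1, 8):
            p = SpreadingParams(beta=0.2, mu=0.4, horizon=t)
            s = tdc_scores(chain_forward, p).vector(chain_forward.nodes)
            if prev is not None:
                assert np.all(s >= prev - 1e-15)
            prev = s

    def test_beta_zero_scores_zero_and_mu_irrelevant_at_horizon_one(
        self, chain_forward
    ):
        s0 = tdc_scores(chain_forward, SpreadingParams(0.0, 0.5, 5))
        assert all(v == 0.0 for v in s0.scores.values())
        a = tdc_scores(chain_forward, SpreadingParams(0.3, 0.0, 1)).vector()
        b = tdc_scores(chain_forward, SpreadingParams(0.3, 0.9, 1)).vector()
        assert np.allclose(a, b, atol=1e-15)

    def test_linear_coupling_overestimates_monte_carlo(self):
        """The cumulative x_i(t) dominates the simulated ever-infected
        probability (linear coupling ignores contact saturation)."""
        rng = np.random.default_rng(31)
        net = random_er_network(rng, n_max=8, l_max=4, n_min=5, l_min=3)
        p = SpreadingParams(beta=0.4, mu=0.2, horizon=4)
        runs = 4000
        seed = net.nodes[0]
        mc = ever_infected_probabilities(net, seed, p, runs=runs, rng_seed=9)
        x = infection_recursion(net, seed, p).final
        se = np.sqrt(mc * (1 - mc) / runs)
        others = np.arange(net.n_nodes) != net.node_index[seed]
        assert np.all(x[others] >= mc[others] - 3 * se[others])


class TestNormalization:
    def test_min_max_examples(self):
        from tdcnet import CentralityScores

        s = CentralityScores({"a": 1.0, "b": 2.0, "c": 3.0}, "x")
        assert normalize_scores(s).vector(["a", "b", "c"]).tolist() == [0, 0.5, 1]
        const = CentralityScores({"a": 5.0, "b": 5.0}, "x")
        assert normalize_scores(const).vector(["a", "b"]).tolist() == [0, 0]

    def test_normalization_preserves_order_and_range(self):
        from tdcnet import CentralityScores

        rng = np.random.default_rng(2)
        v = rng.normal(size=20)
        s = CentralityScores(dict(zip(range(20), v)), "x")
        out = normalize_scores(s).vector(list(range(20)))
        assert out.min() >= 0 and out.max() <= 1
        assert np.array_equal(np.argsort(out), np.argsort(v))

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=25
        )
    )
    def test_normalization_bounded_and_order_preserving(self, values):
        from tdcnet import CentralityScores

        s = CentralityScores(dict(enumerate(map(float, values))), "x")
        out = normalize_scores(s).vector(range(len(values)))
        assert np.all(out >= 0.0) and np.all(out <= 1.0)
        # monotone: never inverts an order (ties may appear through rounding)
        v = np.asarray(values)
        for i in range(len(v)):
            for j in range(i + 1, len(v)):
                assert np.sign(out[i] - out[j]) * np.sign(v[i] - v[j]) >= 0

    def test_shift_adds_one(self):
        from tdcnet import CentralityScores

        s = CentralityScores({"a": 0.0, "b": 0.5, "c": 1.0}, "x")
        assert shifted_scores(s).vector(["a", "b", "c"]).tolist() == [1.0, 1.5, 2.0]
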