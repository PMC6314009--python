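import numpy as np
import pytest

import symptomnet as sn
from symptomnet.data_prep import SymptomData
from symptomnet.elasso import (
    EstimationConfig,
    ebic,
    fit_node,
    lambda_max,
    logistic_lasso_path,
    symmetrize,
)
from symptomnet.errors import ConfigError, DataError
from symptomnet.ising import state_matrix


def sample_data(params, n, seed, labels=None):
    matrix = sn.sample(params, n, seed)
    labels = labels or [f"A{i + 1}" for i in range(params.p)]
    return SymptomData(matrix, labels, ["alcohol"] * params.p)


class TestLassoPath:
    def test_lambda_max_kkt_full_shrinkage(self):
        rng = np.random.default_rng(0)
        params = sn.IsingParameters(rng.normal(size=4) * 0.5, np.zeros((4, 4)))
        m = sn.sample(params, 2000, 1)
        y, X = m[:, 0].astype(float), m[:, 1:].astype(float)
        lam = lambda_max(y, X)
        path = logistic_lasso_path(y, X, np.array([lam]))
        assert np.all(path.coefs[0] == 0.0)
        ybar = y.mean()
        assert path.intercepts[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    def test_unpenalized_matches_newton_oracle(self, chain4_params):
        m = sn.sample(chain4_params, 2000, 2)
        y, X = m[:, 0].astype(float), m[:, 1:].astype(float)
        path = logistic_lasso_path(y, X, np.array([0.0]), tol=1e-10)
        import statsmodels.api as sm

        fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-12)
        ours = np.r_[path.intercepts[0], path.coefs[0]]
        assert np.abs(ours - fit.params).max() < 1e-6
        assert path.loglik[0] == pytest.approx(fit.llf, abs=1e-6)

    def test_binary_and_dense_kernels_agree(self, chain4_params):
        from symptomnet import _kernels

        m = sn.sample(chain4_params, 1000, 3)
        y, X = m[:, 0].astype(float), m[:, 1:].astype(float)
        lam = lambda_max(y, X)
        lams = np.geomspace(lam, 0.01 * lam, 40)
        path = logistic_lasso_path(y, X, lams, tol=1e-9)
        dense = _kernels.lasso_path_dense(
            np.ascontiguousarray(X), y, np.ones(y.size), lams, 1e-9, 200, 2000
        )
        assert np.abs(path.coefs - dense[1]).max() < 1e-6

    def test_spurious_coefficients_vanish_under_independence(self):
        def max_spurious(n, seed):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 2, size=(n, 5)).astype(float)
            y = rng.integers(0, 2, size=n).astype(float)
            lam = lambda_max(y, X)
            path = logistic_lasso_path(y, X, np.geomspace(lam, 0.01 * lam, 50))
            return np.abs(path.coefs).max()

        small = np.mean([max_spurious(500, 40 + s) for s in range(3)])
        large = np.mean([max_spurious(5000, 40 + s) for s in range(3)])
        # spurious magnitudes stay modest and shrink with n
        assert large < 0.2
        assert large < small

    def test_increasing_lambda_path_rejected(self):
        y = np.array([0.0, 1, 0, 1])
        X = np.array([[0.0], [1], [1], [0]])
        with pytest.raises(ConfigError):
            logistic_lasso_path(y, X, np.array([0.1, 0.2]))

    def test_constant_column_rejected(self):
        y = np.array([0.0, 1, 0, 1])
        X = np.ones((4, 1))
        with pytest.raises(DataError, match="constant"):
            logistic_lasso_path(y, X, np.array([0.1]))


class TestEbic:
    def test_null_model(self):
        assert ebic(-50.0, 0, 100, 10, 0.25) == pytest.approx(100.0)

    def test_gamma_zero_is_bic(self):
        assert ebic(-50.0, 3, 100, 10, 0.0) == pytest.approx(100.0 + 3 * np.log(100))

    def test_arithmetic_example(self):
        expected = 200.0 + 3 * np.log(1000) + 1.5 * np.log(20)
        assert ebic(-100.0, 3, 1000, 20, 0.25) == pytest.approx(expected, abs=1e-12)

    def test_bad_n(self):
        with pytest.raises(ConfigError):
            ebic(-1.0, 0, 0, 5, 0.25)


class TestFitNode:
    def test_independence_selects_null_model(self):
        rng = np.random.default_rng(0)
        tau = np.array([-1.2, -0.3, 0.2, -0.8, -0.5])
        params = sn.IsingParameters(tau, np.zeros((5, 5)))
        clean = 0
        for rep in range(20):
            data = sample_data(params, 2000, seed=1000 + rep)
            fits = [fit_node(data, node) for node in range(5)]
            if all((fit.coefficients == 0).all() for fit in fits):
                clean += 1
        assert clean >= 19  # >= 95% of replicates

    def test_chain_recovers_exact_neighbors(self, chain4_params):
        exact = 0
        for rep in range(20):
            data = sample_data(chain4_params, 5000, seed=2000 + rep)
            ok = True
            for node in range(4):
                fit = fit_node(data, node)
                selected = set(np.flatnonzero(fit.coefficients != 0.0))
                truth = set(np.flatnonzero(chain4_params.omega[node] != 0.0))
                ok &= selected == truth
            exact += ok
        assert exact >= 18  # >= 90% of replicates

    def test_recovered_chain_signs_positive(self, chain4_params):
        data = sample_data(chain4_params, 5000, seed=3000)
        for node in range(4):
            fit = fit_node(data, node)
            for j in np.flatnonzero(fit.coefficients != 0.0):
                if chain4_params.omega[node, j] > 0:
                    assert fit.coefficients[j] > 0

    def test_self_edge_impossible(self, chain4_params):
        data = sample_data(chain4_params, 1000, seed=5)
        fit = fit_node(data, 2)
        assert fit.coefficients[2] == 0.0

    def test_ebic_tie_prefers_larger_lambda(self, chain4_params):
        data = sample_data(chain4_params, 1000, seed=6)
        fit = fit_node(data, 0)
        ebics = fit.ebic_path
        first_min = int(np.argmin(ebics))
        assert fit.selected_index == first_min
        assert fit.selected_lambda == fit.lambdas[first_min]

    def test_separation_flag_and_warning(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, size=200)
        x2 = rng.integers(0, 2, size=200)
        while np.array_equal(x2, y):
            x2 = rng.integers(0, 2, size=200)
        data = SymptomData(
            np.column_stack([y, y, x2]), ["A1", "A2", "A3"], ["alcohol"] * 3
        )
        lam = 0.3
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = fit_node(data, 0, lambdas=np.array([lam, 0.0]))
        assert fit.separation_flag
        assert np.all(np.abs(fit.coefficients) <= 30.0)
        assert fit.selected_lambda == lam


class TestSymmetrize:
    def test_and_rule_mean(self):
        B = np.array([[0.0, 0.6], [0.4, 0.0]])
        W = symmetrize(B, "AND")
        assert W[0, 1] == pytest.approx(0.5)
        assert W[1, 0] == pytest.approx(0.5)

    def test_and_rule_drops_one_sided(self):
        B = np.array([[0.0, 0.6], [0.0, 0.0]])
        assert np.all(symmetrize(B, "AND") == 0.0)

    def test_or_rule_keeps_one_sided_halved(self):
        B = np.array([[0.0, 0.6], [0.0, 0.0]])
        W = symmetrize(B, "OR")
        assert W[0, 1] == pytest.approx(0.3)


class TestEstimateNetwork:
    def test_output_exactly_symmetric_zero_diagonal(self, small_data):
        data, _ = small_data
        graph, params = sn.estimate_network(data)
        assert np.array_equal(graph.weights, graph.weights.T)
        assert np.all(np.diag(graph.weights) == 0.0)
        assert np.array_equal(params.omega, graph.weights)

    def test_zero_variance_column_rejected(self):
        m = np.column_stack([np.ones(100, dtype=np.int8),
                             np.random.default_rng(0).integers(0, 2, 100),
                             np.random.default_rng(1).integers(0, 2, 100)])
        data = SymptomData(m, ["A1", "A2", "A3"], ["alcohol"] * 3)
        with pytest.raises(DataError, match="zero-variance"):
            sn.estimate_network(data)

    def test_weighted_enumeration_oracle_recovers_parameters(self, chain4_params):
        # fit the exactly enumerated 16-state dataset, each state weighted by
        # its probability: lambda=0 fits must recover tau and omega
        probs = sn.enumerate_pmf(chain4_params)
        bits = state_matrix(4)
        data = SymptomData(bits, ["A1", "A2", "A3", "A4"], ["alcohol"] * 4)
        graph, params = sn.estimate_network(
            data,
            EstimationConfig(tol=1e-12),
            sample_weight=probs * 16,
            lambdas=np.array([0.0]),
        )
        assert np.abs(params.tau - chain4_params.tau).max() < 1e-6
        assert np.abs(graph.weights - chain4_params.omega).max() < 1e-6

    def test_support_recovery_improves_with_n(self):
        config = sn.GeneratorConfig(
            n=10,
            cluster_sizes=(4, 4),
            seed=0,
            n_bridge_edges=1,
            within_edge_probability=0.4,
            target_endorsement_rates=np.linspace(0.15, 0.5, 8),
        )
        truth = sn.make_study_like(config)
        true_edges = truth.edge_set()
        recalls = {500: [], 4000: []}
        for seed in range(10):
            for n in (500, 4000):
                matrix = sn.sample(truth.params, n, seed=seed * 2 + (n == 4000))
                data = SymptomData(matrix, truth.symptom_labels, truth.cluster_labels)
                graph, _ = sn.estimate_network(data)
                found = {(i, j) for i, j, _ in graph.edges()}
                recalls[n].append(len(found & true_edges) / len(true_edges))
        assert np.mean(recalls[4000]) >= np.mean(recalls[500])

    def test_study_like_false_cross_edges(self, study_runs):
        false_counts = []
        for run in study_runs:
            truth, graph = run["truth"], run["graph"]
            n_a = run["config"].cluster_sizes[0]
            cross_true = {
                (i, j) for (i, j) in truth.edge_set() if (i < n_a) != (j < n_a)
            }
            est_cross = {
                (i, j) for i, j, _ in graph.edges() if (i < n_a) != (j < n_a)
            }
            false_counts.append(len(est_cross - cross_true))
        assert np.median(false_counts) <= 2
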