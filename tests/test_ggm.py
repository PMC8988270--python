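import numpy as np
import pytest

from helpers import chain_model, sample_gaussian
from symptomnet import (EstimationError, ebic_score, estimate_network,
                        glasso_fit, partials_from_precision,
                        sample_correlation)


class TestSampleCorrelation:
    def test_identical_and_negated_columns(self):
        x = np.array([1.0, 2.0, 4.0, 3.0, 0.0])
        R = sample_correlation(np.column_stack([x, x, -x])).R
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)

    def test_matches_hand_pearson_formula(self):
        X = np.array([[0, 1, 2], [1, 3, 1], [2, 2, 0], [3, 0, 1], [1, 1, 3]], float)
        R = sample_correlation(X).R
        for i in range(3):
            for j in range(3):
                xi, xj = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert R[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_column_named(self):
        X = np.ones((5, 2))
        X[:, 1] = [1, 2, 3, 4, 5]
        with pytest.raises(EstimationError, match="item 1"):
            sample_correlation(X)


class TestGlassoFit:
    def test_identity_input_gives_identity_precision(self):
        for lam in (0.0, 0.1, 0.5):
            np.testing.assert_allclose(glasso_fit(np.eye(4), lam), np.eye(4), atol=1e-8)

    def test_full_penalty_gives_diagonal_solution(self, rng):
        X = rng.standard_normal((100, 5))
        X[:, 1] += 0.8 * X[:, 0]
        R = sample_correlation(X).R
        lam_max = np.abs(R[np.triu_indices(5, 1)]).max()
        Theta = glasso_fit(R, lam_max * 1.0001)
        off = Theta[np.triu_indices(5, 1)]
        assert np.all(off == 0.0)

    def test_unpenalized_fit_inverts_correlation(self, rng):
        X = rng.standard_normal((500, 4))
        X[:, 1] += 0.5 * X[:, 0]
        R = sample_correlation(X).R
        Theta = glasso_fit(R, 0.0, tol=1e-9)
        np.testing.assert_allclose(Theta, np.linalg.inv(R), atol=1e-5)

    def test_agrees_with_sklearn_backend(self, rng):
        # independent established solver as cross-check: same edge sets,
        # near-identical values
        sklearn = pytest.importorskip("sklearn.covariance")
        X = rng.standard_normal((400, 6))
        X[:, 1] += 0.6 * X[:, 0]
        X[:, 4] -= 0.5 * X[:, 2]
        R = sample_correlation(X).R
        iu = np.triu_indices(6, 1)
        for lam in (0.3, 0.1, 0.03):
            ours = glasso_fit(R, lam, tol=1e-7)
            _, theirs = sklearn.graphical_lasso(R, alpha=lam, tol=1e-10, max_iter=2000)
            assert set(map(tuple, np.argwhere(ours != 0))) == set(
                map(tuple, np.argwhere(np.abs(theirs) > 1e-8)))
            np.testing.assert_allclose(ours[iu], theirs[iu], atol=2e-3)


class TestPartialsFromPrecision:
    def test_hand_worked_tridiagonal(self):
        Theta = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]])
        W = partials_from_precision(Theta)
        assert W[0, 1] == pytest.approx(0.5)
        assert W[1, 2] == pytest.approx(0.5)
        assert W[0, 2] == 0.0
        assert np.all(np.diag(W) == 0)

    def test_diagonal_precision_gives_empty_network(self):
        np.testing.assert_array_equal(partials_from_precision(np.diag([1.0, 2.0, 3.0])),
                                      np.zeros((3, 3)))

    def test_sign_flip_and_zero_propagation(self):
        Theta = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert partials_from_precision(Theta)[0, 1] < 0
        Theta[0, 1] = Theta[1, 0] = 0.0
        assert partials_from_precision(Theta)[0, 1] == 0.0

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(EstimationError):
            partials_from_precision(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestEbicScore:
    def test_diagonal_theta_has_zero_penalty(self):
        R = np.eye(3)
        Theta = np.eye(3)
        # EBIC = -2*ll; ll = (n/2)(logdet - trace) = (n/2)(0 - 3)
        assert ebic_score(Theta, R, n=50, gamma=0.5) == pytest.approx(3 * 50)

    def test_gamma_zero_reduces_to_bic(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        Theta = np.linalg.inv(R)
        n = 100
        bic = ebic_score(Theta, R, n, gamma=0.0)
        ebic = ebic_score(Theta, R, n, gamma=0.5)
        assert ebic - bic == pytest.approx(4 * 0.5 * 1 * np.log(2))

    def test_hand_coded_formula_p2(self):
        # independent evaluation of the formula
        r, n, gamma = 0.5, 100, 0.5
        R = np.array([[1.0, r], [r, 1.0]])
        Theta = np.linalg.inv(R)
        logdet = np.log(np.linalg.det(Theta))
        ll = (n / 2) * (logdet - np.trace(R @ Theta))
        expected = -2 * ll + 1 * np.log(n) + 4 * gamma * 1 * np.log(2)
        assert ebic_score(Theta, R, n, gamma) == pytest.approx(expected, abs=1e-8)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(EstimationError):
            ebic_score(np.array([[1.0, 2.0], [2.0, 1.0]]), np.eye(2), 10)


class TestEstimateNetwork:
    def test_chain_recovery_with_sign(self, rng):
        K, partials = chain_model(p=6, partial=0.4)
        X = sample_gaussian(K, 2000, rng)
        net = estimate_network(X)
        true_edges = {(i, i + 1) for i in range(5)}
        est_edges = {(i, j) for i, j, _ in net.edges()}
        assert true_edges <= est_edges
        for i, j in true_edges:
            assert np.sign(net.W[i, j]) == np.sign(partials[i, j])

    def test_independent_items_give_near_empty_network(self, rng):
        X = rng.standard_normal((1000, 6))
        net = estimate_network(X)
        assert net.nonzero_edge_count <= 2

    def test_edge_count_non_increasing_in_penalty(self, rng):
        K, _ = chain_model(p=5, partial=0.35)
        X = sample_gaussian(K, 400, rng)
        net = estimate_network(X)
        # lambda_path is descending, so counts must be non-decreasing
        assert np.all(np.diff(net.edge_count_path) >= 0)

    def test_row_permutation_invariance(self, rng):
        K, _ = chain_model(p=4, partial=0.3)
        X = sample_gaussian(K, 300, rng)
        net1 = estimate_network(X)
        net2 = estimate_network(X[rng.permutation(300)])
        np.testing.assert_allclose(net1.W, net2.W, atol=1e-10)

    def test_selected_lambda_minimizes_ebic_path(self, rng):
        K, _ = chain_model(p=4, partial=0.3)
        X = sample_gaussian(K, 500, rng)
        net = estimate_network(X)
        assert net.lambda_selected == net.lambda_path[np.argmin(net.ebic_path)]
        assert net.nonzero_edge_count == net.edge_count_path[np.argmin(net.ebic_path)]

    def test_sensitivity_grows_with_sample_size(self, rng):
        # specificity stays high, sensitivity rises with n
        K, _ = chain_model(p=6, partial=0.25)
        true_edges = {(i, i + 1) for i in range(5)}
        sens = []
        for n in (100, 500, 2000):
            hits = spur = 0
            for s in range(3):
                X = sample_gaussian(K, n, np.random.default_rng(100 * n + s))
                est = {(i, j) for i, j, _ in estimate_network(X).edges()}
                hits += len(est & true_edges)
                spur += len(est - true_edges)
            sens.append(hits / (3 * len(true_edges)))
            assert spur / 3 <= 2  # high specificity at every n
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] == 1.0
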