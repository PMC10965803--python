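import numpy as np
import pytest
import scipy.optimize

import tcrpred.kmer_features as kf
from tcrpred import _penalized as pen
from tcrpred.homology_kernel import HomologyKernel, kernel_matrix, psd_project
from tcrpred.model import (
    ModelError,
    TrainedModel,
    fit_binary,
    fit_continuous,
    predict,
)


def _zero_kernel(n):
    return HomologyKernel(np.zeros((n, n)), [f"i{j}" for j in range(n)], "BLOSUM62", True)


def _feature_matrix(vals, k=3):
    n, p = vals.shape
    return kf.FeatureMatrix(
        np.abs(vals), [f"K{j:02d}" for j in range(p)], [f"i{i}" for i in range(n)], k
    )


class TestContinuous:
    def test_linear_recovery_without_kernel_signal(self):
        # Y = 2 - X1 + noise; Z pure noise; K = 0
        rng = np.random.default_rng(0)
        n = 200
        X = rng.normal(size=(n, 1))
        Z = _feature_matrix(rng.normal(size=(n, 8)))
        y = 2.0 - X[:, 0] + 0.3 * rng.normal(size=n)
        m = fit_continuous(y, X, Z, _zero_kernel(n), lambda0="cv", random_state=1)
        assert m.beta0 == pytest.approx(2.0, abs=0.15)
        assert m.beta[0] == pytest.approx(-1.0, abs=0.15)
        assert np.allclose(m.alpha, 0.0)
        assert len(m.selected_features) <= 2  # noise features mostly excluded

    def test_lambda1_rule_recorded(self):
        rng = np.random.default_rng(1)
        n = 60
        X = rng.normal(size=(n, 1))
        Z = _feature_matrix(rng.normal(size=(n, 5)))
        y = rng.normal(size=n)
        m = fit_continuous(y, X, Z, _zero_kernel(n), lambda0=1.0)
        p_final = len(m.selected_features)
        assert m.lambda_kernel_history[-1] == pytest.approx((p_final + 1 + 1) / n)
        # support never re-enters: the kernel penalty is non-increasing
        assert all(np.diff(m.lambda_kernel_history) <= 1e-12)

    def test_reduces_to_ols_plus_ridge_alpha(self, small_pool):
        # no penalty, one iteration, scaled-identity kernel
        rng = np.random.default_rng(2)
        n, p = 40, 3
        X = rng.normal(size=(n, 2))
        Z = _feature_matrix(rng.normal(size=(n, p)))
        y = rng.normal(size=n)
        K = HomologyKernel(0.5 * np.eye(n), [f"i{j}" for j in range(n)], "BLOSUM62", True)
        m = fit_continuous(
            y, X, Z, K, lambda0=0.0, max_iter=1, kernel_eigen_floor=0.0
        )
        A = np.column_stack([np.ones(n), X, Z.values])
        theta = np.linalg.lstsq(A, y, rcond=None)[0]
        assert m.beta0 == pytest.approx(theta[0], abs=1e-8)
        assert m.beta == pytest.approx(theta[1:3], abs=1e-8)
        assert m.gamma == pytest.approx(theta[3:], abs=1e-8)
        resid = y - A @ theta
        lam1 = (p + 2 + 1) / n
        assert m.alpha == pytest.approx(resid / (lam1 + 0.5), abs=1e-8)

    def test_alpha_stationarity_condition(self, small_pool):
        # K(res - K alpha) = lambda1 K alpha for the closed-form update
        rng = np.random.default_rng(3)
        n = 12
        A = rng.normal(size=(n, n))
        Kv = A @ A.T / n
        res = rng.normal(size=n)
        lam1 = 0.37
        alpha = np.linalg.solve(lam1 * np.eye(n) + Kv, res)
        lhs = Kv @ (res - Kv @ alpha)
        rhs = lam1 * Kv @ alpha
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_closed_form_matches_numerical_minimizer(self):
        rng = np.random.default_rng(4)
        n = 5
        A = rng.normal(size=(n, n))
        Kv = A @ A.T  # full-rank PSD
        res = rng.normal(size=n)
        lam1 = 0.25
        closed = np.linalg.solve(lam1 * np.eye(n) + Kv, res)

        def obj(a):
            r = res - Kv @ a
            return r @ r + lam1 * a @ Kv @ a

        opt = scipy.optimize.minimize(obj, np.zeros(n), method="BFGS", tol=1e-12)
        assert np.allclose(closed, opt.x, atol=1e-6)

    def test_nonfinite_inputs_error(self):
        n = 20
        y = np.zeros(n)
        y[3] = np.nan
        Z = _feature_matrix(np.ones((n, 2)))
        with pytest.raises(ModelError, match="non-finite"):
            fit_continuous(y, np.zeros((n, 1)), Z, _zero_kernel(n), lambda0=1.0)


class TestPartialLassoKKT:
    def test_subgradient_conditions(self):
        rng = np.random.default_rng(5)
        n, p = 80, 10
        U = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.normal(size=(n, p))
        y = Z[:, 0] * 2 - Z[:, 3] + rng.normal(size=n)
        lam = 20.0
        b, g = pen.partial_lasso(y, U, Z, lam, tol=1e-12)
        resid = y - U @ b - Z @ g
        grad = 2.0 * Z.T @ resid  # d/dgamma of sum of squares is -2 Z'resid
        for j in range(p):
            if g[j] != 0:
                assert grad[j] == pytest.approx(lam * np.sign(g[j]), abs=1e-6 * lam)
            else:
                assert abs(grad[j]) <= lam * (1 + 1e-6)
        # unpenalized block is exactly orthogonal to the residual
        assert np.allclose(U.T @ resid, 0.0, atol=1e-8)


class TestBinary:
    def test_working_response_formula(self):
        # Delta = 0: Y_w = Delta + (Y - 0.5)/0.25 = +-2
        pi = 0.5
        assert 0 + (1 - pi) / (pi * (1 - pi)) == pytest.approx(2.0)
        assert 0 + (0 - pi) / (pi * (1 - pi)) == pytest.approx(-2.0)

    def test_rejects_nonbinary_outcome(self):
        n = 30
        Z = _feature_matrix(np.ones((n, 2)))
        with pytest.raises(ModelError, match="0/1"):
            fit_binary(np.linspace(0, 2, n), None, Z, _zero_kernel(n), lambda2=1.0)

    def test_converges_and_records_trace(self):
        rng = np.random.default_rng(6)
        n = 120
        X = rng.normal(size=(n, 1))
        Zv = rng.normal(size=(n, 6))
        eta = -0.5 + X[:, 0] + 2.0 * Zv[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        Z = kf.FeatureMatrix(Zv, [f"K{j}" for j in range(6)], [f"i{i}" for i in range(n)], 3)
        m = fit_binary(y, X, Z, _zero_kernel(n), lambda2="cv", random_state=0)
        assert m.outcome_type == "binary"
        assert len(m.loss_trace) == m.n_iterations
        assert "K1" in m.selected_features
        assert all(np.diff(m.lambda_kernel_history) <= 1e-12)

    @pytest.mark.parametrize("symmetrized", [False, True])
    def test_alpha_update_matches_dense_solve(self, small_pool, symmetrized):
        # one iteration of the binary path against a dense full-space solve
        # of the corresponding linear system, on a positive-definite kernel
        rng = np.random.default_rng(7)
        reps = small_pool[:25]
        n = 25
        Kp = psd_project(kernel_matrix(reps))
        Kv = 0.5 * np.eye(n) + 0.5 * Kp.values  # strictly PD
        K = HomologyKernel(Kv, list(Kp.individual_ids), "BLOSUM62", True)
        X = rng.normal(size=(n, 1))
        Zv = np.abs(rng.normal(size=(n, 4)))
        Z = kf.FeatureMatrix(Zv, [f"K{j}" for j in range(4)], list(K.individual_ids), 3)
        eta = 0.5 * X[:, 0] + Zv[:, 1] - Zv[:, 2]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        lam2 = 5.0
        m = fit_binary(
            y, X, Z, K, lambda2=lam2, max_iter=1, kernel_eigen_floor=0.0,
            symmetrized_alpha_update=symmetrized,
        )
        # rebuild the iteration-1 quantities independently
        U = np.column_stack([np.ones(n), X])
        b0, g0 = pen.l1_logistic_partial(y, U, Zv, lam2)
        delta = U @ b0 + Zv @ g0
        pi = np.clip(1 / (1 + np.exp(-delta)), 1e-8, 1 - 1e-8)
        nu = pi * (1 - pi)
        yw = delta + (y - pi) / nu
        b1, g1 = pen.partial_lasso(yw, U, Zv, 2.0 * lam2, weights=nu)
        keep = g1 != 0
        lam_t = (keep.sum() + 1 + 1) / n
        resid = yw - U @ b1 - Zv[:, keep] @ g1[keep]
        sq = np.sqrt(nu)
        if symmetrized:
            A = lam_t * np.eye(n) + sq[:, None] * Kv * sq[None, :]
        else:
            A = lam_t * np.eye(n) + sq[:, None] * Kv
        expected = np.linalg.solve(A, sq * resid)
        assert np.allclose(m.alpha, expected, atol=1e-7)


class TestPredict:
    @pytest.fixture()
    def fitted(self, small_pool):
        rng = np.random.default_rng(8)
        reps = small_pool[:25]
        K = psd_project(kernel_matrix(reps))
        Z = kf.quantile_scale(kf.build_feature_matrix(reps, 3), 0.75)
        n = len(reps)
        X = rng.normal(size=(n, 1))
        y = 1.0 + X[:, 0] + rng.normal(size=n)
        m = fit_continuous(y, X, Z, K, lambda0="cv", random_state=2)
        return m, reps, K, Z, X

    def test_recomputation_oracle(self, fitted):
        m, reps, K, Z, X = fitted
        rng = np.random.default_rng(9)
        X_new = rng.normal(size=(5, 1))
        Z_new = rng.uniform(size=(5, len(m.selected_features)))
        K_new = rng.uniform(size=(5, len(reps)))
        res = predict(m, X_new, Z_new=Z_new, K_cross=K_new)
        manual = m.beta0 + X_new @ m.beta + Z_new @ m.gamma + K_new @ m.alpha
        assert np.allclose(res.linear, manual, atol=1e-10)

    def test_training_rows_reproduce_fitted_values(self, fitted):
        m, reps, K, Z, X = fitted
        sel = [Z.feature_names.index(c) for c in m.selected_features]
        res = predict(m, X, Z_new=Z.values[:, sel], K_cross=K.values)
        assert np.allclose(res.linear, m.fitted_values, atol=1e-8)

    def test_kmer_rebuild_matches_matrix_path(self, fitted):
        m, reps, K, Z, X = fitted
        res_a = predict(m, X, reps_new=reps, reps_train=reps)
        sel = [Z.feature_names.index(c) for c in m.selected_features]
        res_b = predict(
            m, X, Z_new=Z.values[:, sel], K_cross=kernel_matrix(reps).values
        )
        assert np.allclose(res_a.linear, res_b.linear, atol=1e-10)

    def test_order_invariance(self, fitted):
        m, reps, K, Z, X = fitted
        new = reps[:6]
        Xn = X[:6]
        res = predict(m, Xn, reps_new=new, reps_train=reps)
        res_rev = predict(m, Xn[::-1], reps_new=new[::-1], reps_train=reps)
        assert np.allclose(res.linear, res_rev.linear[::-1], atol=1e-12)

    def test_binary_probability_half_at_zero(self):
        m = TrainedModel(
            outcome_type="binary", beta0=0.0, beta=np.zeros(0), covariate_names=[],
            gamma=np.zeros(0), selected_features=[], alpha=np.zeros(2),
            training_ids=["a", "b"], lambda_penalty=1.0, lambda_kernel_history=[],
            loss_trace=[], n_iterations=0, converged=True,
            feature_scale_factors=None, k=3, weight_by_abundance=True,
            substitution="BLOSUM62",
        )
        res = predict(m, np.zeros((3, 0)), Z_new=np.zeros((3, 0)), K_cross=np.zeros((3, 2)))
        assert res.probability == pytest.approx([0.5, 0.5, 0.5])
        assert res.label.tolist() == [1, 1, 1]

    def test_serialization_round_trip(self, fitted, tmp_path):
        m, reps, K, Z, X = fitted
        p = tmp_path / "model.json"
        m.save(p)
        back = TrainedModel.load(p)
        assert back.selected_features == m.selected_features
        assert back.beta0 == pytest.approx(m.beta0)
        assert np.allclose(back.alpha, m.alpha)
        assert np.allclose(back.gamma, m.gamma)
        assert back.lambda_penalty == m.lambda_penalty
        res_a = predict(m, X[:3], Z_new=np.zeros((3, len(m.selected_features))), K_cross=K.values[:3])
        res_b = predict(back, X[:3], Z_new=np.zeros((3, len(m.selected_features))), K_cross=K.values[:3])
        assert np.allclose(res_a.linear, res_b.linear)
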