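import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.cross_decomposition import PLSRegression

from nircal import (
    PLSParams,
    SVRParams,
    choose_n_latent,
    cv_rmse,
    fit_pls,
    fit_svr,
    predict,
    tenfold_split,
)
from nircal.models import pls_cv_rmse_path, pls_cv_rmse_path_gram


class TestTenfoldSplit:
    def test_singleton_folds(self):
        f = tenfold_split(10, 10, seed=3)
        assert sorted(f.sizes()) == [1] * 10

    def test_118_samples_max_balanced(self):
        f = tenfold_split(118, 10, seed=0)
        assert sorted(f.sizes()) == [11, 11] + [12] * 8
        assert np.bincount(f.fold_of, minlength=10).sum() == 118

    def test_seed_determinism(self):
        a = tenfold_split(50, 10, seed=5)
        b = tenfold_split(50, 10, seed=5)
        c = tenfold_split(50, 10, seed=6)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert not np.array_equal(a.fold_of, c.fold_of)

    def test_every_sample_held_out_once(self):
        f = tenfold_split(37, 5, seed=1)
        seen = np.concatenate([f.test_indices(k) for k in range(5)])
        assert sorted(seen.tolist()) == list(range(37))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            tenfold_split(5, 10, seed=0)


class TestPLS:
    def test_rank_one_exact_fit(self, rng):
        x1 = rng.normal(0, 1, 30)
        X = np.column_stack([x1, np.zeros(30), np.zeros(30)])
        y = 2 * x1
        m = fit_pls(X, y, PLSParams(n_latent=1))
        np.testing.assert_allclose(m.train_predictions, y, atol=1e-8)

    def test_full_components_equal_least_squares(self, rng):
        # oracle: OLS through the normal equations on a full-rank 20x5 design
        for _ in range(5):
            X = rng.normal(0, 1, (20, 5))
            y = rng.normal(0, 1, 20)
            m = fit_pls(X, y, PLSParams(n_latent=5))
            Xc = np.column_stack([X, np.ones(20)])
            beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
            np.testing.assert_allclose(m.train_predictions, Xc @ beta, atol=1e-6)

    def test_agrees_with_sklearn_pls(self, rng):
        X = rng.normal(0, 1, (25, 8))
        y = X @ rng.normal(0, 1, 8) + rng.normal(0, 0.2, 25)
        ours = fit_pls(X, y, PLSParams(n_latent=3))
        ref = PLSRegression(n_components=3, scale=False).fit(X, y.reshape(-1, 1))
        np.testing.assert_allclose(
            ours.train_predictions, ref.predict(X).ravel(), atol=1e-8
        )

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_pls(rng.normal(0, 1, (10, 3)), np.full(10, 2.0), PLSParams(n_latent=1))

    def test_rank_bound_enforced(self, rng):
        X = rng.normal(0, 1, (6, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(X, rng.normal(0, 1, 6), PLSParams(n_latent=6))

    def test_prediction_scales_with_response(self, rng):
        X = rng.normal(0, 1, (15, 4))
        y = X @ [1, 2, 0, -1] + rng.normal(0, 0.1, 15)
        m1 = fit_pls(X, y, PLSParams(n_latent=2))
        m3 = fit_pls(X, 3 * y, PLSParams(n_latent=2))
        Xnew = rng.normal(0, 1, (5, 4))
        np.testing.assert_allclose(3 * predict(m1, Xnew), predict(m3, Xnew), atol=1e-8)

    def test_column_mismatch_rejected(self, rng):
        m = fit_pls(rng.normal(0, 1, (10, 4)), rng.normal(0, 1, 10), PLSParams(n_latent=1))
        with pytest.raises(ValueError, match="columns"):
            predict(m, rng.normal(0, 1, (3, 5)))


class TestChooseNLatent:
    def test_recovers_generative_rank_two(self):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            T = r.normal(0, 1, (60, 2))
            P = r.normal(0, 1, (2, 12))
            X = T @ P + r.normal(0, 0.02, (60, 12))
            y = T @ [1.5, -1.0] + r.normal(0, 0.02, 60)
            folds = tenfold_split(60, 10, seed)
            if choose_n_latent(X, y, folds, 8) == 2:
                hits += 1
        assert hits >= 6

    def test_single_candidate(self, rng):
        X = rng.normal(0, 1, (20, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 20)
        assert choose_n_latent(X, y, tenfold_split(20, 5, 0), 1) == 1

    def test_pure_noise_still_in_range(self, rng):
        X = rng.normal(0, 1, (30, 5))
        y = rng.normal(0, 1, 30)
        k = choose_n_latent(X, y, tenfold_split(30, 10, 0), 5)
        assert 1 <= k <= 5


class TestGramPath:
    def test_matches_primal_path(self, rng):
        X = rng.normal(0, 1, (40, 30))
        y = rng.normal(0, 1, 40) + X[:, 0]
        folds = tenfold_split(40, 5, 3)
        primal = pls_cv_rmse_path(X, y, folds, 8)
        dual = pls_cv_rmse_path_gram(X @ X.T, y, folds, 8)
        np.testing.assert_allclose(primal, dual, atol=1e-9)


def _svr_dual_qp(X, y, C, epsilon):
    """Independent epsilon-SVR dual solve (SLSQP on the 2m-variable QP)."""
    m = len(y)
    K = X @ X.T

    def obj(z):
        a, astar = z[:m], z[m:]
        d = a - astar
        return 0.5 * d @ K @ d + epsilon * z.sum() - y @ d

    def jac(z):
        a, astar = z[:m], z[m:]
        Kd = K @ (a - astar)
        return np.concatenate([Kd + epsilon - y, -Kd + epsilon + y])

    cons = {"type": "eq", "fun": lambda z: z[:m].sum() - z[m:].sum(),
            "jac": lambda z: np.concatenate([np.ones(m), -np.ones(m)])}
    res = minimize(obj, np.zeros(2 * m), jac=jac, method="SLSQP",
                   bounds=[(0, C)] * 2 * m, constraints=[cons],
                   options={"maxiter": 500, "ftol": 1e-12})
    d = res.x[:m] - res.x[m:]
    # intercept from margin support vectors
    margin = [(i, np.sign(d[i])) for i in range(m) if 1e-6 < abs(d[i]) < C - 1e-6]
    f0 = K @ d
    if margin:
        b = float(np.mean([y[i] - f0[i] - s * epsilon for i, s in margin]))
    else:
        b = float(np.mean(y - f0))
    return d, b


class TestSVR:
    def test_near_interpolation_of_linear_data(self, rng):
        x = rng.normal(0, 1, 40)
        X = x.reshape(-1, 1)
        y = 3 * x + 1
        m = fit_svr(X, y, SVRParams(C=1.0, epsilon=0.01))
        res = np.sqrt(np.mean((m.train_predictions - y) ** 2))
        # epsilon lives on the standardized-y scale; map the bound back
        assert res <= 0.01 * y.std() + 1e-3

    def test_constant_response_predicts_inside_tube(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = np.full(10, 7.0)
        m = fit_svr(X, y, SVRParams(C=1.0, epsilon=0.5))
        np.testing.assert_allclose(m.train_predictions, 7.0, atol=0.5)

    def test_agrees_with_independent_qp_solution(self, rng):
        X = rng.normal(0, 1, (10, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(0, 0.3, 10)
        C, eps = 1.0, 0.1
        m = fit_svr(X, y, SVRParams(C=C, epsilon=eps))
        # replicate the model's internal standardization, then solve the dual
        Xs = (X - m.x_mean) / m.x_scale
        ys = (y - m.y_mean) / m.y_scale
        d, b = _svr_dual_qp(Xs, ys, C, eps)
        qp_pred = (Xs @ Xs.T @ d + b) * m.y_scale + m.y_mean
        np.testing.assert_allclose(m.train_predictions, qp_pred, atol=1e-4)

    def test_kkt_inside_tube_has_zero_dual_weight(self, rng):
        X = rng.normal(0, 1, (25, 3))
        y = X @ [2.0, 0.0, -1.0] + rng.normal(0, 0.5, 25)
        m = fit_svr(X, y, SVRParams(C=1.0, epsilon=0.2))
        est = m.estimator
        Xs = (X - m.x_mean) / m.x_scale
        ys = (y - m.y_mean) / m.y_scale
        resid = np.abs(est.predict(Xs) - ys)
        inside = np.setdiff1d(np.arange(25), est.support_)
        assert np.all(resid[inside] <= 0.2 + 1e-6)


class TestCvRmse:
    def test_mean_only_model_approaches_response_sd(self, rng):
        X = rng.normal(0, 1, (200, 3))
        y = rng.normal(10, 2, 200)
        # a huge tube forces the flat (mean) solution
        val = cv_rmse(SVRParams(C=1.0, epsilon=50.0), X, y, tenfold_split(200, 10, 0))
        assert val == pytest.approx(y.std(), rel=0.05)

    def test_noiseless_linear_data_is_interpolated(self, rng):
        X = rng.normal(0, 1, (30, 1))
        y = 4.0 * X[:, 0]
        val = cv_rmse(PLSParams(n_latent=1), X, y, tenfold_split(30, 10, 0))
        assert val < 1e-6

    def test_fold_consistent_permutation_invariance(self, rng):
        X = rng.normal(0, 1, (40, 5))
        y = X @ [1, 0, 2, 0, -1] + rng.normal(0, 0.5, 40)
        folds = tenfold_split(40, 5, 2)
        perm = rng.permutation(40)
        from nircal.models import FoldAssignment

        permuted = FoldAssignment(40, 5, folds.fold_of[perm], folds.seed)
        a = cv_rmse(PLSParams(n_latent=2), X, y, folds)
        b = cv_rmse(PLSParams(n_latent=2), X[perm], y[perm], permuted)
        assert a == pytest.approx(b, abs=1e-10)
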