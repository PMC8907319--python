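"""Calibration models (PLS1, linear epsilon-SVR) and cross-validation.

PLS is implemented as single-response NIPALS with column mean-centering
and no unit-variance scaling of X (SNV has already put spectra on a
common scale). The deflation produces orthogonal scores, so the rotation
matrix R = W (P'W)^-1 yields the regression vector for every truncated
component count in one pass — which is what makes latent-count selection
inside a cross-validated fitness loop affordable.

SVR is the linear epsilon-insensitive machine at fixed penalty C
(default 1); columns of X and the response are standardized before the
solve and predictions are mapped back. The quadratic program is
delegated to scikit-learn's libsvm backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
from sklearn.svm import SVR as _SkSVR

__all__ = [
    "PLSParams",
    "SVRParams",
    "FoldAssignment",
    "FittedModel",
    "tenfold_split",
    "fit_pls",
    "fit_svr",
    "fit_model",
    "choose_n_latent",
    "predict",
    "cv_rmse",
    "pls_cv_rmse_path",
    "pls_cv_rmse_path_gram",
]


@dataclass(frozen=True)
class PLSParams:
    """PLS1 hyperparameters.

    ``n_latent=None`` means "choose by cross-validation up to max_latent"
    wherever a fold assignment is available.
    """

    n_latent: int | None = None
    max_latent: int = 15

    def __post_init__(self):
        if self.n_latent is not None and self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if self.max_latent < 1:
            raise ValueError("max_latent must be >= 1")


@dataclass(frozen=True)
class SVRParams:
    """Linear epsilon-SVR hyperparameters; epsilon is on the standardized-y scale."""

    C: float = 1.0
    epsilon: float = 0.1

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class FoldAssignment:
    """A max-balanced random partition of sample indices into folds."""

    n_samples: int
    n_folds: int
    fold_of: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.where(self.fold_of != fold)[0]

    def sizes(self) -> list[int]:
        return [int((self.fold_of == f).sum()) for f in range(self.n_folds)]


def tenfold_split(n_samples: int, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomly assign samples to folds whose sizes differ by at most 1.

    With 118 samples and 10 folds this yields eight folds of 12 and two of
    11, so every sample is held out exactly once across the rotation.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_samples < n_folds:
        raise ValueError(f"n_samples ({n_samples}) < n_folds ({n_folds})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    base, extra = divmod(n_samples, n_folds)
    fold_of = np.empty(n_samples, dtype=int)
    start = 0
    for f in range(n_folds):
        size = base + (1 if f < extra else 0)
        fold_of[perm[start : start + size]] = f
        start += size
    return FoldAssignment(n_samples, n_folds, fold_of, seed)


@dataclass
class FittedModel:
    """A trained calibration model reduced to what prediction needs."""

    kind: str  # "pls" | "svr"
    params: object
    n_vars: int
    coef: np.ndarray | None = None  # pls: regression vector on raw X
    intercept: float = 0.0
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0
    estimator: object = None  # svr: the fitted sklearn machine
    train_predictions: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_comp: int):
    """NIPALS deflation for one response; returns means, rotations and loadings.

    May stop early if the X'y covariance vanishes (the fit is then already
    exact at the achieved number of components).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(np.abs(Xc).max(), 1.0) * max(np.abs(yc).max(), 1.0)
    W = np.zeros((p, n_comp))
    P = np.zeros((p, n_comp))
    q = np.zeros(n_comp)
    k = 0
    for _ in range(n_comp):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * scale:
            break
        w /= nw
        t = Xc @ w
        tt = t @ t
        if tt <= 1e-28 * scale**2:
            break
        p_a = Xc.T @ t / tt
        q_a = (yc @ t) / tt
        Xc -= np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, k], P[:, k], q[k] = w, p_a, q_a
        k += 1
    W, P, q = W[:, :k], P[:, :k], q[:k]
    if k:
        # P'W is upper triangular for NIPALS, so truncations nest
        R = W @ np.linalg.inv(np.triu(P.T @ W))
    else:
        R = np.zeros((p, 0))
    return x_mean, y_mean, R, q, k


def fit_pls(X, y, p: PLSParams, folds: "FoldAssignment | None" = None) -> FittedModel:
    """Fit PLS1 with ``p.n_latent`` components (or CV-chosen when None)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    n, nv = X.shape
    if n != y.size or n < 2:
        raise ValueError("X rows and y length must match and be >= 2")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; nothing to calibrate")
    rank_bound = min(n - 1, nv)
    if p.n_latent is None:
        if folds is None:
            n_latent = min(p.max_latent, rank_bound)
        else:
            n_latent = choose_n_latent(X, y, folds, min(p.max_latent, rank_bound))
    else:
        n_latent = p.n_latent
        if n_latent > rank_bound:
            raise ValueError(
                f"n_latent {n_latent} exceeds rank bound min(n-1, n_vars)={rank_bound}"
            )
    x_mean, y_mean, R, q, k = _nipals_pls1(X, y, n_latent)
    coef = R @ q
    intercept = float(y_mean - x_mean @ coef)
    model = FittedModel(
        kind="pls",
        params=PLSParams(n_latent=n_latent, max_latent=p.max_latent),
        n_vars=nv,
        coef=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=float(y_mean),
        extra={"n_components_effective": k},
    )
    model.train_predictions = predict(model, X)
    return model


def fit_svr(X, y, p: SVRParams) -> FittedModel:
    """Fit a linear epsilon-SVR on standardized columns and response."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if X.shape[0] != y.size or X.shape[0] < 2:
        raise ValueError("X rows and y length must match and be >= 2")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=0)) or 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    est = _SkSVR(kernel="linear", C=p.C, epsilon=p.epsilon, tol=1e-6)
    est.fit(Xs, ys)
    model = FittedModel(
        kind="svr",
        params=p,
        n_vars=X.shape[1],
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        estimator=est,
    )
    model.train_predictions = predict(model, X)
    return model


def fit_model(spec, X, y, folds: "FoldAssignment | None" = None) -> FittedModel:
    """Dispatch on the parameter type: PLSParams -> PLS1, SVRParams -> SVR."""
    if isinstance(spec, PLSParams):
        return fit_pls(X, y, spec, folds=folds)
    if isinstance(spec, SVRParams):
        return fit_svr(X, y, spec)
    raise TypeError(f"unknown model spec {type(spec).__name__}")


def predict(m: FittedModel, X) -> np.ndarray:
    """Predict the response (%) for new spectra rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != m.n_vars:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model was trained on {m.n_vars}"
        )
    if m.kind == "pls":
        return X @ m.coef + m.intercept
    if m.kind == "svr":
        Xs = (X - m.x_mean) / m.x_scale
        return m.estimator.predict(Xs) * m.y_scale + m.y_mean
    raise ValueError(f"unknown model kind {m.kind!r}")


def pls_cv_rmse_path(X, y, folds: FoldAssignment, max_latent: int) -> np.ndarray:
    """Pooled out-of-fold RMSE for every component count 1..max_latent.

    One NIPALS run per fold at max_latent components serves the whole
    path: held-out scores T = (Xv - x_mean) R give the k-component
    prediction as y_mean + T[:, :k] q[:k].
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    max_latent = min(max_latent, X.shape[1])
    sq = np.zeros(max_latent)
    for f in range(folds.n_folds):
        tr = folds.train_indices(f)
        te = folds.test_indices(f)
        cap = min(max_latent, tr.size - 1)
        x_mean, y_mean, R, q, k = _nipals_pls1(X[tr], y[tr], cap)
        T = (X[te] - x_mean) @ R
        pred = np.full(te.size, y_mean)
        for a in range(max_latent):
            if a < k:
                pred = pred + T[:, a] * q[a]
            sq[a] += np.sum((pred - y[te]) ** 2)
    return np.sqrt(sq / y.size)


@numba.njit(cache=True)
def _gram_cv_path_kernel(K, y, fold_of, n_folds, max_latent):  # pragma: no cover
    n_all = y.shape[0]
    sq = np.zeros(max_latent)
    for f in range(n_folds):
        ntr = 0
        for i in range(n_all):
            if fold_of[i] != f:
                ntr += 1
        nte = n_all - ntr
        tr = np.empty(ntr, np.int64)
        te = np.empty(nte, np.int64)
        a = 0
        b = 0
        for i in range(n_all):
            if fold_of[i] == f:
                te[b] = i
                b += 1
            else:
                tr[a] = i
                a += 1
        # slice the Gram blocks and center by the training means
        Kc = np.empty((ntr, ntr))
        for i in range(ntr):
            for j in range(ntr):
                Kc[i, j] = K[tr[i], tr[j]]
        Kx = np.empty((nte, ntr))
        for i in range(nte):
            for j in range(ntr):
                Kx[i, j] = K[te[i], tr[j]]
        col_mean = np.zeros(ntr)
        for i in range(ntr):
            for j in range(ntr):
                col_mean[j] += Kc[i, j]
        col_mean /= ntr
        grand = col_mean.mean()
        for i in range(ntr):
            for j in range(ntr):
                Kc[i, j] += grand - col_mean[i] - col_mean[j]
        xrow_mean = np.zeros(nte)
        for i in range(nte):
            for j in range(ntr):
                xrow_mean[i] += Kx[i, j]
        xrow_mean /= ntr
        for i in range(nte):
            for j in range(ntr):
                Kx[i, j] += grand - col_mean[j] - xrow_mean[i]
        ymean = 0.0
        for i in range(ntr):
            ymean += y[tr[i]]
        ymean /= ntr
        yc = np.empty(ntr)
        for i in range(ntr):
            yc[i] = y[tr[i]] - ymean
        pred = np.full(nte, ymean)
        scale = max(np.abs(Kc).max(), 1.0) * max(np.abs(yc).max(), 1.0)
        cap = min(max_latent, ntr - 1)
        alive = True
        for comp in range(max_latent):
            if alive and comp < cap:
                Ky = Kc @ yc
                nw2 = yc @ Ky
                if nw2 > 1e-28 * scale * scale:
                    nw = np.sqrt(nw2)
                    t = Ky / nw
                    tt = t @ t
                    if tt > 1e-28 * scale * scale:
                        q = (yc @ t) / tt
                        tstar = (Kx @ yc) / nw
                        u = (Kc @ t) / tt
                        tu = t @ u
                        w = Kx @ t / tt
                        for i in range(ntr):
                            for j in range(ntr):
                                Kc[i, j] += (
                                    (tu / tt) * t[i] * t[j]
                                    - t[i] * u[j]
                                    - u[i] * t[j]
                                )
                        for i in range(nte):
                            for j in range(ntr):
                                Kx[i, j] += (
                                    (tu / tt) * tstar[i] * t[j]
                                    - tstar[i] * u[j]
                                    - w[i] * t[j]
                                )
                        for i in range(ntr):
                            yc[i] -= q * t[i]
                        for i in range(nte):
                            pred[i] += q * tstar[i]
                    else:
                        alive = False
                else:
                    alive = False
            for i in range(nte):
                d = pred[i] - y[te[i]]
                sq[comp] += d * d
    return np.sqrt(sq / n_all)


def pls_cv_rmse_path_gram(K: np.ndarray, y, folds: FoldAssignment, max_latent: int) -> np.ndarray:
    """Pooled out-of-fold RMSE path computed from the uncentered Gram matrix.

    ``K = X @ X.T`` over all samples in ``folds``. Mathematically identical
    to :func:`pls_cv_rmse_path` (dual-form NIPALS with double-centering),
    but the per-evaluation cost scales with n^2 instead of n*p — the
    workhorse behind segment-mask fitness, where K is a sum of precomputed
    per-segment Gram matrices. Compiled; the primal path serves as the
    independent reference in tests.
    """
    K = np.ascontiguousarray(K, dtype=float)
    y = np.ascontiguousarray(np.asarray(y, dtype=float))
    fold_of = np.ascontiguousarray(folds.fold_of, dtype=np.int64)
    return _gram_cv_path_kernel(K, y, fold_of, folds.n_folds, max_latent)


def choose_n_latent(X, y, folds: FoldAssignment, max_latent: int) -> int:
    """Latent count in [1, max_latent] minimizing pooled RMSECV; ties go low."""
    if max_latent < 1:
        raise ValueError("max_latent must be >= 1")
    path = pls_cv_rmse_path(X, y, folds, max_latent)
    return int(np.argmin(path)) + 1


def cv_rmse(spec, X, y, folds: FoldAssignment) -> float:
    """Cross-validated RMSE pooling all out-of-fold residuals.

    For ``PLSParams(n_latent=None)`` this is the minimum of the RMSECV
    path over 1..max_latent — i.e. the fitness of the variable subset at
    its best latent count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(spec, PLSParams):
        cap = min(spec.max_latent, X.shape[1])
        if spec.n_latent is None:
            return float(pls_cv_rmse_path(X, y, folds, cap).min())
        sq = 0.0
        for f in range(folds.n_folds):
            tr, te = folds.train_indices(f), folds.test_indices(f)
            k = min(spec.n_latent, tr.size - 1, X.shape[1])
            m = fit_pls(X[tr], y[tr], PLSParams(n_latent=k))
            sq += np.sum((predict(m, X[te]) - y[te]) ** 2)
        return float(np.sqrt(sq / y.size))
    sq = 0.0
    for f in range(folds.n_folds):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        m = fit_model(spec, X[tr], y[tr])
        sq += np.sum((predict(m, X[te]) - y[te]) ** 2)
    return float(np.sqrt(sq / y.size))
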