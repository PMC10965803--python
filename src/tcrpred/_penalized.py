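"""Partially penalized regression solvers.

Everywhere in the pipeline the intercept and the adjusting covariates X are
*never* penalized while the feature coefficients gamma carry an L1 (or L2)
penalty.  For squared-error losses this is solved exactly by projecting the
penalized block onto the orthocomplement of the unpenalized block:

    min_{b, g} ||W^{1/2}(y - U b - Z g)||^2 + lam |g|_1
    <=>  g = argmin ||M W^{1/2} y - M W^{1/2} Z g||^2 + lam |g|_1,

with M the residual-maker of W^{1/2} U; b is then recovered by weighted
least squares.  The projected problem is handed to scikit-learn's
coordinate-descent Lasso.  The logistic variants wrap these solvers in an
IRLS (proximal-Newton) loop whose fixed point minimizes the penalized
log-likelihood.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

_SIGMOID_CLIP = (1e-8, 1.0 - 1e-8)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def clipped_sigmoid(x: np.ndarray) -> np.ndarray:
    return np.clip(sigmoid(x), *_SIGMOID_CLIP)


def _weighted(y, U, Z, weights):
    if weights is None:
        return y, U, Z
    sw = np.sqrt(weights)
    return y * sw, U * sw[:, None], (Z * sw[:, None] if Z.size else Z)


def _project_out(U, *mats):
    """Residualize each matrix/vector against the column space of U."""
    Q, _ = np.linalg.qr(U)
    return [m - Q @ (Q.T @ m) for m in mats]


def _recover_unpenalized(y, U, Z, gamma, weights):
    yt, Ut, Zt = _weighted(y, U, Z, weights)
    resid = yt - (Zt @ gamma if Z.size else 0.0)
    b, *_ = np.linalg.lstsq(Ut, resid, rcond=None)
    return b


def partial_lasso(
    y: np.ndarray,
    U: np.ndarray,
    Z: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize sum_i w_i (y_i - U_i b - Z_i g)^2 + lam |g|_1 exactly.

    Returns ``(b, g)``; ``U`` must contain the intercept column.
    """
    n = len(y)
    if Z.size == 0:
        g = np.zeros(Z.shape[1])
        return _recover_unpenalized(y, U, Z, g, weights), g
    yt, Ut, Zt = _weighted(y, U, Z, weights)
    yp, Zp = _project_out(Ut, yt, Zt)
    if lam <= 0:
        A = np.hstack([Ut, Zt])
        theta, *_ = np.linalg.lstsq(A, yt, rcond=None)
        return theta[: U.shape[1]], theta[U.shape[1] :]
    las = Lasso(
        alpha=lam / (2.0 * n), fit_intercept=False, tol=tol, max_iter=max_iter
    )
    las.fit(Zp, yp)
    g = las.coef_.copy()
    return _recover_unpenalized(y, U, Z, g, weights), g


def partial_lasso_cv(
    y: np.ndarray,
    U: np.ndarray,
    Z: np.ndarray,
    weights: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 60,
) -> float:
    """Pick the L1 penalty by K-fold CV on the projected design.

    Returns lam on the sum-of-squares scale used by :func:`partial_lasso`.
    """
    n = len(y)
    yt, Ut, Zt = _weighted(y, U, Z, weights)
    yp, Zp = _project_out(Ut, yt, Zt)
    cv = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    las = LassoCV(
        alphas=n_alphas, cv=cv, fit_intercept=False, tol=1e-6, max_iter=50_000
    )
    las.fit(Zp, yp)
    return float(las.alpha_ * 2.0 * n)


def partial_ridge(
    y: np.ndarray,
    U: np.ndarray,
    Z: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize sum_i w_i (y_i - U_i b - Z_i g)^2 + lam ||g||^2 in closed form."""
    r = U.shape[1]
    p = Z.shape[1]
    yt, Ut, Zt = _weighted(y, U, Z, weights)
    A = np.hstack([Ut, Zt]) if p else Ut
    D = np.zeros(r + p)
    D[r:] = lam
    G = A.T @ A + np.diag(D)
    theta = np.linalg.solve(G, A.T @ yt)
    return theta[:r], theta[r:]


def _logloss(y, eta):
    pi = clipped_sigmoid(eta)
    return float(-(y * np.log(pi) + (1 - y) * np.log(1 - pi)).sum())


def l1_logistic_partial(
    y: np.ndarray,
    U: np.ndarray,
    Z: np.ndarray,
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """L1-penalized logistic regression with unpenalized block U.

    Minimizes sum_i [-y_i eta_i + log(1 + e^{eta_i})] + lam |g|_1 by IRLS:
    each step solves the weighted-least-squares surrogate
    sum nu_i (yw_i - eta_i)^2 + 2 lam |g|_1 whose fixed point is the exact
    penalized-likelihood optimum.  Step-halving guards the rare
    non-decreasing step.
    """
    b = np.zeros(U.shape[1])
    g = np.zeros(Z.shape[1])
    eta = U @ b + (Z @ g if Z.size else 0.0)
    obj = _logloss(y, eta) + lam * np.abs(g).sum()
    for _ in range(max_iter):
        pi = clipped_sigmoid(eta)
        nu = pi * (1 - pi)
        yw = eta + (y - pi) / nu
        b_new, g_new = partial_lasso(yw, U, Z, 2.0 * lam, weights=nu)
        step = 1.0
        for _ in range(30):
            b_try = b + step * (b_new - b)
            g_try = g + step * (g_new - g)
            eta_try = U @ b_try + (Z @ g_try if Z.size else 0.0)
            obj_try = _logloss(y, eta_try) + lam * np.abs(g_try).sum()
            if obj_try <= obj + 1e-12:
                break
            step *= 0.5
        b, g, eta = b_try, g_try, eta_try
        if abs(obj - obj_try) <= tol * (1.0 + abs(obj)):
            obj = obj_try
            break
        obj = obj_try
    return b, g


def l2_logistic_partial(
    y: np.ndarray,
    U: np.ndarray,
    Z: np.ndarray,
    lam: float,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalized logistic regression with unpenalized block U."""
    r, p = U.shape[1], Z.shape[1]
    b = np.zeros(r)
    g = np.zeros(p)
    eta = U @ b + (Z @ g if Z.size else 0.0)
    obj = _logloss(y, eta) + lam * (g @ g)
    for _ in range(max_iter):
        pi = clipped_sigmoid(eta)
        nu = pi * (1 - pi)
        yw = eta + (y - pi) / nu
        b_new, g_new = partial_ridge(yw, U, Z, lam, weights=nu)
        step = 1.0
        for _ in range(30):
            b_try = b + step * (b_new - b)
            g_try = g + step * (g_new - g)
            eta_try = U @ b_try + (Z @ g_try if Z.size else 0.0)
            obj_try = _logloss(y, eta_try) + lam * (g_try @ g_try)
            if obj_try <= obj + 1e-12:
                break
            step *= 0.5
        b, g, eta = b_try, g_try, eta_try
        if abs(obj - obj_try) <= tol * (1.0 + abs(obj)):
            obj = obj_try
            break
        obj = obj_try
    return b, g


def choose_l1_logistic_lambda(
    y: np.ndarray,
    U: np.ndarray,
    Z: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """Select the binary-path L1 penalty by CV on the linearized problem.

    Fits the unpenalized covariate-only logistic model, forms the working
    response and IRLS weights there, and runs weighted LassoCV on the
    projected design.  Returns lam on the log-likelihood scale (the lam of
    :func:`l1_logistic_partial`).
    """
    b, _ = l1_logistic_partial(y, U, np.empty((len(y), 0)), 0.0)
    eta = U @ b
    pi = clipped_sigmoid(eta)
    nu = pi * (1 - pi)
    yw = eta + (y - pi) / nu
    lam_ssq = partial_lasso_cv(yw, U, Z, weights=nu, n_folds=n_folds, seed=seed)
    return lam_ssq / 2.0
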