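"""Comparator models and evaluation metrics.

Baselines mirror the standard practice the kernel model is compared
against: a covariate-only GLM (optionally with Shannon entropy as a
diversity summary), and penalized regressions on the screened k-mer matrix
(tcrLASSO / tcrRidge) with the adjusting covariates left unpenalized.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from . import _penalized
from ._penalized import clipped_sigmoid
from .kmer_features import FeatureMatrix
from .repertoire_io import Repertoire


class BaselineError(Exception):
    pass


def shannon_entropy(rep: Repertoire, base: float | None = None) -> float:
    """Diversity of a repertoire: -sum q_j log q_j over clone proportions.

    Natural log by default; pass ``base=2`` for bits.  Zero-proportion terms
    contribute 0.
    """
    w = rep.abundances
    if w.size == 0:
        raise ValueError("repertoire is empty")
    q = w / w.sum()
    q = q[q > 0]
    h = float(-(q * np.log(q)).sum())
    return h / math.log(base) if base else h


@dataclasses.dataclass
class GLMModel:
    """Unpenalized linear/logistic regression on covariates only."""

    outcome_type: str
    params: np.ndarray  # [intercept, covariates...]
    bse: np.ndarray
    covariate_names: list[str]

    def linear_predictor(self, X_new) -> np.ndarray:
        Xm = _to_matrix(X_new, self.covariate_names)
        return self.params[0] + Xm @ self.params[1:]

    def predict(self, X_new) -> np.ndarray:
        lin = self.linear_predictor(X_new)
        return clipped_sigmoid(lin) if self.outcome_type == "binary" else lin


def _to_matrix(X, names) -> np.ndarray:
    if X is None:
        return np.empty((0, len(names)))
    if isinstance(X, pd.DataFrame):
        return X[names].to_numpy(dtype=float) if names else np.empty((len(X), 0))
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def _check_rank(A: np.ndarray, names: list[str]) -> None:
    if A.shape[1] == 0:
        return
    _, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [names[j] for j in np.where(bad)[0]]
        raise BaselineError(f"design matrix is rank deficient; collinear columns: {cols}")


def fit_basic_glm(y: np.ndarray, X, outcome_type: str = "continuous") -> GLMModel:
    """Fit the covariate-only GLM (intercept + X, no repertoire features)."""
    y = np.asarray(y, dtype=float)
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    elif X is None:
        names, Xm = [], np.empty((len(y), 0))
    else:
        Xm = np.asarray(X, dtype=float)
        Xm = Xm[:, None] if Xm.ndim == 1 else Xm
        names = [f"x{j + 1}" for j in range(Xm.shape[1])]
    A = np.hstack([np.ones((len(y), 1)), Xm])
    _check_rank(A, ["(intercept)"] + names)
    if outcome_type == "continuous":
        res = sm.OLS(y, A).fit()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, A).fit(disp=0)
    return GLMModel(outcome_type, np.asarray(res.params), np.asarray(res.bse), names)


@dataclasses.dataclass
class PenalizedModel:
    """Penalized regression of the outcome on [X, Z_screened]."""

    outcome_type: str
    penalty: str  # "lasso" or "ridge"
    intercept: float
    beta: np.ndarray
    covariate_names: list[str]
    gamma: np.ndarray
    feature_names: list[str]
    lam: float

    def linear_predictor(self, X_new, Z_new) -> np.ndarray:
        Xm = _to_matrix(X_new, self.covariate_names)
        Z = np.asarray(Z_new, dtype=float)
        return self.intercept + Xm @ self.beta + Z @ self.gamma

    def predict(self, X_new, Z_new) -> np.ndarray:
        lin = self.linear_predictor(X_new, Z_new)
        return clipped_sigmoid(lin) if self.outcome_type == "binary" else lin


_RIDGE_GRID = np.logspace(-3, 5, 25)


def _cv_ridge(y, U, Z, outcome_type, n_folds, seed):
    cv = KFold(n_splits=min(n_folds, len(y)), shuffle=True, random_state=seed)
    best, best_loss = _RIDGE_GRID[0], np.inf
    for lam in _RIDGE_GRID:
        loss = 0.0
        for tr, te in cv.split(y):
            if outcome_type == "continuous":
                b, g = _penalized.partial_ridge(y[tr], U[tr], Z[tr], lam)
                pred = U[te] @ b + Z[te] @ g
                loss += float(((y[te] - pred) ** 2).sum())
            else:
                b, g = _penalized.l2_logistic_partial(y[tr], U[tr], Z[tr], lam)
                eta = U[te] @ b + Z[te] @ g
                loss += _penalized._logloss(y[te], eta)
        if loss < best_loss:
            best, best_loss = lam, loss
    return float(best)


def fit_tcr_penalized(
    y: np.ndarray,
    X,
    Z_screened: FeatureMatrix,
    penalty: str = "lasso",
    outcome_type: str = "continuous",
    lam: float | str = "cv",
    cv_seed: int = 0,
) -> PenalizedModel:
    """tcrLASSO / tcrRidge: regress Y on [X, Z_screened], penalizing only the
    feature coefficients; lambda by 10-fold cross-validation."""
    if penalty not in ("lasso", "ridge"):
        raise ValueError("penalty must be 'lasso' or 'ridge'")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    elif X is None:
        names, Xm = [], np.empty((n, 0))
    else:
        Xm = np.asarray(X, dtype=float)
        Xm = Xm[:, None] if Xm.ndim == 1 else Xm
        names = [f"x{j + 1}" for j in range(Xm.shape[1])]
    U = np.hstack([np.ones((n, 1)), Xm])
    _check_rank(U, ["(intercept)"] + names)
    Z = Z_screened.values

    if outcome_type == "continuous":
        if penalty == "lasso":
            if lam == "cv":
                lam = _penalized.partial_lasso_cv(y, U, Z, seed=cv_seed)
            b, g = _penalized.partial_lasso(y, U, Z, float(lam))
        else:
            if lam == "cv":
                lam = _cv_ridge(y, U, Z, outcome_type, 10, cv_seed)
            b, g = _penalized.partial_ridge(y, U, Z, float(lam))
    else:
        if penalty == "lasso":
            if lam == "cv":
                lam = _penalized.choose_l1_logistic_lambda(y, U, Z, seed=cv_seed)
            b, g = _penalized.l1_logistic_partial(y, U, Z, float(lam))
        else:
            if lam == "cv":
                lam = _cv_ridge(y, U, Z, outcome_type, 10, cv_seed)
            b, g = _penalized.l2_logistic_partial(y, U, Z, float(lam))
    return PenalizedModel(
        outcome_type, penalty, float(b[0]), b[1:].copy(), names,
        g.copy(), list(Z_screened.feature_names), float(lam),
    )


@dataclasses.dataclass
class EvalReport:
    """Prediction-performance summary on a test set."""

    outcome_type: str
    n_test: int
    classification_error: float | None = None
    auc: float | None = None
    mse: float | None = None
    per_replicate: pd.DataFrame | None = None


def evaluate(predictions, truth, outcome_type: str) -> EvalReport:
    """Classification error (0.5 threshold) and AUC for binary outcomes;
    MSE for continuous.  AUC uses the Mann-Whitney statistic (midranks for
    ties); it is reported as missing when the truth has a single class."""
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("predictions and truth must be aligned")
    n = len(truth)
    if outcome_type == "continuous":
        return EvalReport("continuous", n, mse=float(np.mean((pred - truth) ** 2)))
    err = float(np.mean((pred >= 0.5).astype(float) != truth))
    if len(np.unique(truth)) < 2:
        warnings.warn("AUC undefined: truth has a single class", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score(truth, pred))
    return EvalReport("binary", n, classification_error=err, auc=auc)
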