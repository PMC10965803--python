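"""TCRpred estimation: alternating penalized regression and kernel update.

The semi-parametric model for individual i with outcome Y_i, adjusting
covariates X_i, extracted features Z_i and repertoire R_i is

    E[Y_i] = pi( beta0 + X_i' beta + Z_i' gamma + h(R_i) ),

with pi the identity (continuous) or logistic (binary) link, an L1 penalty
on gamma for feature selection and an RKHS penalty on h.  By the representer
theorem h(R_i) = K_i' alpha for the repertoire-homology kernel K, so fitting
alternates between

* a partially penalized (weighted) lasso of the kernel-adjusted response on
  [X, Z^(t-1)] — features whose coefficient is zeroed never re-enter — and
* a closed-form ridge-type update of alpha with data-driven kernel penalty
  lambda^(t) = (p^(t) + r + 1) / n,

monitored by training MSE (continuous) or cross-entropy (binary) until the
change falls below ``eps``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from . import _penalized
from .homology_kernel import HomologyKernel, kernel_cross
from .kmer_features import FeatureMatrix, extract_kmers
from .repertoire_io import Repertoire
from ._penalized import clipped_sigmoid

MODEL_SCHEMA_VERSION = 1


class ModelError(Exception):
    pass


@dataclasses.dataclass
class TrainedModel:
    """A fitted TCRpred model plus everything needed to score new individuals."""

    outcome_type: str  # "continuous" or "binary"
    beta0: float
    beta: np.ndarray
    covariate_names: list[str]
    gamma: np.ndarray
    selected_features: list[str]
    alpha: np.ndarray
    training_ids: list[str]
    lambda_penalty: float
    lambda_kernel_history: list[float]
    loss_trace: list[float]
    n_iterations: int
    converged: bool
    feature_scale_factors: np.ndarray | None
    k: int
    weight_by_abundance: bool
    substitution: str
    gap_open: float = 10.0
    gap_extend: float = 1.0
    normalize_similarity: bool = True
    kernel_eigen_floor: float = 2.0
    fitted_values: np.ndarray | None = None
    train_repertoires_ref: dict | None = None

    @property
    def r(self) -> int:
        return len(self.beta)

    # -- serialization: a single self-describing text file -----------------
    def save(self, path) -> None:
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "outcome_type": self.outcome_type,
            "beta0": self.beta0,
            "beta": dict(zip(self.covariate_names, map(float, self.beta))),
            "gamma": dict(zip(self.selected_features, map(float, self.gamma))),
            "alpha": [float(a) for a in self.alpha],
            "training_ids": self.training_ids,
            "lambda_penalty": self.lambda_penalty,
            "lambda_kernel_history": self.lambda_kernel_history,
            "loss_trace": self.loss_trace,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "feature_scale_factors": (
                None
                if self.feature_scale_factors is None
                else [float(s) for s in self.feature_scale_factors]
            ),
            "k": self.k,
            "weight_by_abundance": self.weight_by_abundance,
            "substitution": self.substitution,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "normalize_similarity": self.normalize_similarity,
            "kernel_eigen_floor": self.kernel_eigen_floor,
            "train_repertoires_ref": self.train_repertoires_ref,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ModelError(f"unsupported model schema: {doc.get('schema_version')}")
        return cls(
            outcome_type=doc["outcome_type"],
            beta0=doc["beta0"],
            beta=np.array(list(doc["beta"].values()), dtype=float),
            covariate_names=list(doc["beta"].keys()),
            gamma=np.array(list(doc["gamma"].values()), dtype=float),
            selected_features=list(doc["gamma"].keys()),
            alpha=np.array(doc["alpha"], dtype=float),
            training_ids=doc["training_ids"],
            lambda_penalty=doc["lambda_penalty"],
            lambda_kernel_history=doc["lambda_kernel_history"],
            loss_trace=doc["loss_trace"],
            n_iterations=doc["n_iterations"],
            converged=doc["converged"],
            feature_scale_factors=(
                None
                if doc["feature_scale_factors"] is None
                else np.array(doc["feature_scale_factors"], dtype=float)
            ),
            k=doc["k"],
            weight_by_abundance=doc["weight_by_abundance"],
            substitution=doc["substitution"],
            gap_open=doc["gap_open"],
            gap_extend=doc["gap_extend"],
            normalize_similarity=doc["normalize_similarity"],
            kernel_eigen_floor=doc.get("kernel_eigen_floor", 2.0),
            train_repertoires_ref=doc.get("train_repertoires_ref"),
        )


@dataclasses.dataclass
class PredictionResult:
    linear: np.ndarray
    probability: np.ndarray | None = None
    label: np.ndarray | None = None

    @property
    def values(self) -> np.ndarray:
        return self.linear if self.probability is None else self.probability


def _as_X(X, n: int) -> tuple[np.ndarray, list[str]]:
    if X is None:
        return np.empty((n, 0)), []
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


def _range_basis(
    Kv: np.ndarray, floor_factor: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Retained eigenbasis of the (projected) kernel.

    The closed-form alpha update is computed in the span of these
    eigenvectors — the kernel's low-rank eigen-representation.  Two effects
    motivate this.  First, when K has a null space (eigen-truncated kernels
    always do) the null-space components of alpha are unidentified — they
    never touch the training fit h = K alpha — and solving in the full
    space fills them with residual/lambda noise that contaminates
    cross-kernel predictions for new individuals; restricting alpha to
    range(K) is the minimum-norm optimum.  Second, with the data-driven
    kernel penalty lambda = (p + r + 1)/n being small, the full-rank update
    can interpolate the (working) response, starving the feature-selection
    step; ``floor_factor`` > 0 keeps only eigenvalues above
    ``floor_factor * trace(K)/n`` (multiples of the average eigenvalue),
    i.e. the components carrying genuine between-individual structure.
    With ``floor_factor = 0`` and positive-definite K this is exactly the
    printed closed form.
    """
    lam, U = np.linalg.eigh((Kv + Kv.T) / 2.0)
    floor = max(
        float(lam.max()) * 1e-10,
        floor_factor * float(np.clip(lam, 0.0, None).sum()) / Kv.shape[0],
    )
    keep = lam > floor
    if not keep.any():  # K == 0: any alpha gives h == 0; use alpha = 0
        return np.zeros((Kv.shape[0], 0)), np.zeros(0)
    return U[:, keep], lam[keep]


def _check_inputs(y, Xmat, Z, K):
    n = len(y)
    if Xmat.shape[0] != n or Z.values.shape[0] != n or K.values.shape[0] != n:
        raise ModelError("y, X, Z and K must be row-aligned")
    for name, arr in (("Y", y), ("X", Xmat), ("Z", Z.values), ("K", K.values)):
        if not np.all(np.isfinite(arr)):
            raise ModelError(f"non-finite values in {name}")


def fit_continuous(
    y: np.ndarray,
    X,
    Z: FeatureMatrix,
    K: HomologyKernel,
    lambda0: float | str = "cv",
    eps: float = 1e-4,
    max_iter: int = 20,
    random_state: int = 0,
    kernel_eigen_floor: float = 2.0,
) -> TrainedModel:
    """Fit the continuous-outcome model.

    ``Z`` should already be prevalence-filtered (and typically screened);
    ``K`` should be the PSD-projected training kernel.  ``lambda0`` is the
    L1 penalty on gamma (sum-of-squares scale) or ``"cv"`` for 10-fold
    cross-validation at the first iteration, held fixed afterwards.
    ``kernel_eigen_floor`` controls the kernel's low-rank eigenbasis used
    in the alpha update (see :func:`_range_basis`); 0 reproduces the
    full-rank closed form.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xmat, xnames = _as_X(X, n)
    _check_inputs(y, Xmat, Z, K)
    r = Xmat.shape[1]
    U = np.hstack([np.ones((n, 1)), Xmat])
    Kv = K.values

    Zt = Z.values
    names_t = list(Z.feature_names)
    alpha = np.zeros(n)
    if lambda0 == "cv":
        lambda0 = _penalized.partial_lasso_cv(y, U, Zt, seed=random_state)
    lambda0 = float(lambda0)

    U_r, lam_r = _range_basis(Kv, kernel_eigen_floor)
    mse_prev = np.inf
    loss_trace: list[float] = []
    lam1_hist: list[float] = []
    converged = False
    b = np.zeros(r + 1)
    g = np.zeros(0)
    for t in range(1, max_iter + 1):
        y_adj = y - Kv @ alpha
        b, g = _penalized.partial_lasso(y_adj, U, Zt, lambda0)
        keep = g != 0
        Zt = Zt[:, keep]
        names_t = [c for c, kk in zip(names_t, keep) if kk]
        g = g[keep]
        p_t = Zt.shape[1]
        lam1 = (p_t + r + 1) / n
        lam1_hist.append(lam1)
        resid = y - b[0] - Xmat @ b[1:] - (Zt @ g if p_t else 0.0)
        # alpha = (lam1 I + K)^{-1} resid, solved in the kernel's eigenbasis
        alpha = U_r @ ((U_r.T @ resid) / (lam1 + lam_r))
        e = resid - Kv @ alpha
        mse = float(e @ e / n)
        loss_trace.append(mse)
        if abs(mse - mse_prev) <= eps:
            converged = True
            mse_prev = mse
            break
        mse_prev = mse

    if len(loss_trace) >= 2 and any(np.diff(loss_trace) > 0):
        # the alternating scheme has no monotonicity guarantee
        logging.getLogger(__name__).info("non-monotone MSE trace: %s", loss_trace)
    fitted = y - (resid - Kv @ alpha)
    sf = None if Z.scale_factors is None else _select_scales(Z, names_t)
    return TrainedModel(
        outcome_type="continuous",
        beta0=float(b[0]),
        beta=b[1:].copy(),
        covariate_names=xnames,
        gamma=g.copy(),
        selected_features=names_t,
        alpha=alpha,
        training_ids=list(K.individual_ids),
        lambda_penalty=lambda0,
        lambda_kernel_history=lam1_hist,
        loss_trace=loss_trace,
        n_iterations=len(loss_trace),
        converged=converged,
        feature_scale_factors=sf,
        k=Z.k,
        weight_by_abundance=True,
        substitution=K.substitution,
        kernel_eigen_floor=kernel_eigen_floor,
        fitted_values=fitted,
    )


def _select_scales(Z: FeatureMatrix, names: Sequence[str]) -> np.ndarray:
    pos = {c: j for j, c in enumerate(Z.feature_names)}
    return Z.scale_factors[[pos[c] for c in names]]


def fit_binary(
    y: np.ndarray,
    X,
    Z: FeatureMatrix,
    K: HomologyKernel,
    lambda2: float | str = "cv",
    eps: float = 1e-4,
    max_iter: int = 20,
    random_state: int = 0,
    symmetrized_alpha_update: bool = False,
    kernel_eigen_floor: float = 2.0,
) -> TrainedModel:
    """Fit the binary-outcome model by the working-response iteration.

    Each iteration linearizes the log-likelihood at the current linear
    predictor Delta (working response Delta + (Y - pi)/(pi(1-pi)), weights
    nu = pi(1-pi)), runs the weighted partial lasso, and updates alpha via
    (lam I + Om^{1/2} K)^{-1} Om^{1/2} (.), with
    lam^(t) = (p^(t) + r + 1)/n.  Convergence is monitored on the training
    cross-entropy.  ``symmetrized_alpha_update`` switches to the
    (lam I + Om^{1/2} K Om^{1/2})^{-1} variant.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ModelError("binary outcome must be coded 0/1")
    n = len(y)
    Xmat, xnames = _as_X(X, n)
    _check_inputs(y, Xmat, Z, K)
    r = Xmat.shape[1]
    U = np.hstack([np.ones((n, 1)), Xmat])
    Kv = K.values

    if lambda2 == "cv":
        lambda2 = _penalized.choose_l1_logistic_lambda(
            y, U, Z.values, seed=random_state
        )
    lambda2 = float(lambda2)

    # initialization: L1-penalized logistic of Y on [X, Z] (gamma penalized)
    b, g = _penalized.l1_logistic_partial(y, U, Z.values, lambda2)
    Zt = Z.values
    names_t = list(Z.feature_names)
    alpha = np.zeros(n)
    h = np.zeros(n)
    U_r, lam_r = _range_basis(Kv, kernel_eigen_floor)

    e_prev = np.inf
    loss_trace: list[float] = []
    lam_hist: list[float] = []
    converged = False
    for t in range(1, max_iter + 1):
        delta = b[0] + Xmat @ b[1:] + (Zt @ g if Zt.shape[1] else 0.0) + h
        pi = clipped_sigmoid(delta)
        nu = pi * (1 - pi)
        yw = delta + (y - pi) / nu
        y_adj = yw - Kv @ alpha
        b, g = _penalized.partial_lasso(y_adj, U, Zt, 2.0 * lambda2, weights=nu)
        keep = g != 0
        Zt = Zt[:, keep]
        names_t = [c for c, kk in zip(names_t, keep) if kk]
        g = g[keep]
        p_t = Zt.shape[1]
        lam = (p_t + r + 1) / n
        lam_hist.append(lam)
        resid = yw - b[0] - Xmat @ b[1:] - (Zt @ g if p_t else 0.0)
        sq = np.sqrt(nu)
        # alpha = (lam I + Om^{1/2} K)^{-1} Om^{1/2} resid (or the symmetrized
        # variant), solved in the kernel's eigenbasis as for the linear case
        n_r = U_r.shape[1]
        if n_r == 0:
            alpha = np.zeros(n)
        elif symmetrized_alpha_update:
            A = lam * np.eye(n_r) + U_r.T @ ((sq[:, None] * Kv * sq[None, :]) @ U_r)
            alpha = U_r @ scipy.linalg.solve(A, U_r.T @ (sq * resid), assume_a="pos")
        else:
            A = lam * np.eye(n_r) + ((U_r.T * sq) @ U_r) * lam_r[None, :]
            alpha = U_r @ scipy.linalg.solve(A, U_r.T @ (sq * resid))
        h = Kv @ alpha
        ce = float(-np.mean(y * np.log(pi) + (1 - y) * np.log(1 - pi)))
        loss_trace.append(ce)
        if abs(ce - e_prev) <= eps:
            converged = True
            break
        e_prev = ce

    delta = b[0] + Xmat @ b[1:] + (Zt @ g if Zt.shape[1] else 0.0) + h
    sf = None if Z.scale_factors is None else _select_scales(Z, names_t)
    return TrainedModel(
        outcome_type="binary",
        beta0=float(b[0]),
        beta=b[1:].copy(),
        covariate_names=xnames,
        gamma=g.copy(),
        selected_features=names_t,
        alpha=alpha,
        training_ids=list(K.individual_ids),
        lambda_penalty=lambda2,
        lambda_kernel_history=lam_hist,
        loss_trace=loss_trace,
        n_iterations=len(loss_trace),
        converged=converged,
        feature_scale_factors=sf,
        k=Z.k,
        weight_by_abundance=True,
        substitution=K.substitution,
        kernel_eigen_floor=kernel_eigen_floor,
        fitted_values=clipped_sigmoid(delta),
    )


def build_prediction_features(
    model: TrainedModel, reps_new: Sequence[Repertoire]
) -> np.ndarray:
    """Extract the model's selected k-mers from new repertoires, on the
    training scale.  A selected k-mer absent from a repertoire scores 0."""
    Zn = np.zeros((len(reps_new), len(model.selected_features)))
    pos = {c: j for j, c in enumerate(model.selected_features)}
    for i, rep in enumerate(reps_new):
        counts = extract_kmers(rep, model.k, model.weight_by_abundance)
        for km, v in counts.items():
            j = pos.get(km)
            if j is not None:
                Zn[i, j] = v
    if model.feature_scale_factors is not None and Zn.shape[1]:
        Zn = Zn / model.feature_scale_factors
    return Zn


def predict(
    model: TrainedModel,
    X_new,
    reps_new: Sequence[Repertoire] | None = None,
    reps_train: Sequence[Repertoire] | None = None,
    K_cross: np.ndarray | None = None,
    Z_new: np.ndarray | None = None,
) -> PredictionResult:
    """Score new individuals with a fitted model.

    The linear predictor is beta0 + X'beta + Z'gamma + K'alpha, where Z is
    restricted to the selected features (rebuilt from ``reps_new`` unless
    ``Z_new`` is supplied) and K' is the raw cross homology against the
    training repertoires (``kernel_cross`` of ``reps_new`` vs ``reps_train``
    unless ``K_cross`` is supplied).  Binary models additionally return the
    logistic probability and the 0.5-thresholded class.
    """
    if Z_new is None:
        if reps_new is None:
            raise ModelError("need reps_new or Z_new")
        Z_new = build_prediction_features(model, reps_new)
    Z_new = np.asarray(Z_new, dtype=float)
    n_new = Z_new.shape[0]
    if K_cross is None:
        if reps_new is None or reps_train is None:
            raise ModelError("need reps_train (or a precomputed K_cross)")
        if [r.individual_id for r in reps_train] != model.training_ids:
            raise ModelError("training repertoires do not match the model's order")
        K_cross = kernel_cross(
            reps_new, reps_train, model.substitution,
            model.gap_open, model.gap_extend, model.normalize_similarity,
        )
    K_cross = np.asarray(K_cross, dtype=float)
    Xmat, _ = _as_X(X_new, n_new)
    lin = (
        model.beta0
        + Xmat @ model.beta
        + (Z_new @ model.gamma if Z_new.shape[1] else 0.0)
        + K_cross @ model.alpha
    )
    if model.outcome_type == "continuous":
        return PredictionResult(linear=lin)
    prob = clipped_sigmoid(lin)
    return PredictionResult(
        linear=lin, probability=prob, label=(prob >= 0.5).astype(int)
    )
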