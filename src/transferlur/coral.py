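"""CORrelation ALignment (CORAL) for unsupervised transfer of LUR models.

Air-pollution predictors (buffer land-use areas, traffic intensities,
population) have different joint distributions in different cities
(covariate shift). CORAL linearly re-colours the source feature matrix so
its covariance matches the target city's,

    min_A  || A' C_S A - C_T ||_F^2 ,

whose closed-form minimiser is A = C_S^{-1/2} C_T^{1/2}. A ridge regressor
is then fitted on the transformed source features and applied to the raw
(centred) target features — a two-stage procedure that uses **no target
measurements**. Conditional shifts (different emission patterns at equal
covariates) are deliberately not addressed here; see
:mod:`transferlur.ensemble` for the distance-weighted mitigation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge, RidgeCV

__all__ = ["CoralModel", "estimate_covariance", "coral_transform",
           "fit_coral", "predict_coral", "coral_objective"]


def estimate_covariance(X, lambda_reg: float = 0.0) -> np.ndarray:
    """Column-centred sample covariance (denominator n-1) plus ``lambda_reg * I``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 rows")
    C = np.cov(X, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    return C + lambda_reg * np.eye(C.shape[0])


def _sym_power(C: np.ndarray, power: float, eig_floor: float) -> np.ndarray:
    """Matrix power of a symmetric PSD matrix via eigendecomposition.

    Eigenvalues are clipped from below at ``eig_floor`` so near-singular
    covariances (feature tables with many zero buffer columns) stay
    invertible and the result is deterministic.
    """
    w, V = np.linalg.eigh(C)
    w = np.maximum(w, eig_floor)
    return (V * w**power) @ V.T


def coral_transform(C_S: np.ndarray, C_T: np.ndarray,
                    eig_floor: float = 1e-12) -> np.ndarray:
    """Closed-form alignment transform A = C_S^{-1/2} C_T^{1/2}.

    Satisfies A' C_S A = C_T (to numerical tolerance) for symmetric
    positive-definite inputs, i.e. whitening by the source covariance
    followed by re-colouring with the target covariance.
    """
    C_S = np.asarray(C_S, dtype=float)
    C_T = np.asarray(C_T, dtype=float)
    for name, C in (("C_S", C_S), ("C_T", C_T)):
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError(f"{name} must be square")
        if not np.allclose(C, C.T, rtol=1e-8, atol=1e-8):
            raise ValueError(f"{name} is not symmetric")
    return _sym_power(C_S, -0.5, eig_floor) @ _sym_power(C_T, 0.5, eig_floor)


def coral_objective(A: np.ndarray, C_S: np.ndarray, C_T: np.ndarray) -> float:
    """Squared Frobenius alignment objective ||A' C_S A - C_T||_F^2."""
    return float(np.linalg.norm(A.T @ C_S @ A - C_T, ord="fro") ** 2)


@dataclass
class CoralModel:
    """Fitted source-to-target CORAL + ridge model."""

    columns: list[str]
    A: np.ndarray = field(repr=False)
    lambda_reg: float
    mean_source: np.ndarray = field(repr=False)
    mean_target: np.ndarray = field(repr=False)
    scale: np.ndarray = field(repr=False)
    ridge_alpha: float
    ridge_coef: np.ndarray = field(repr=False)
    ridge_intercept: float

    def to_json(self, path) -> None:
        payload = {
            "columns": list(self.columns),
            "A": self.A.tolist(),
            "lambda_reg": self.lambda_reg,
            "mean_source": self.mean_source.tolist(),
            "mean_target": self.mean_target.tolist(),
            "scale": self.scale.tolist(),
            "ridge_alpha": self.ridge_alpha,
            "ridge_coef": self.ridge_coef.tolist(),
            "ridge_intercept": self.ridge_intercept,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CoralModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(columns=d["columns"], A=np.array(d["A"]),
                   lambda_reg=d["lambda_reg"],
                   mean_source=np.array(d["mean_source"]),
                   mean_target=np.array(d["mean_target"]),
                   scale=np.array(d["scale"]),
                   ridge_alpha=d["ridge_alpha"],
                   ridge_coef=np.array(d["ridge_coef"]),
                   ridge_intercept=d["ridge_intercept"])


def _as_matrix(X, columns=None):
    if isinstance(X, pd.DataFrame):
        if columns is not None:
            missing = [c for c in columns if c not in X.columns]
            if missing:
                raise ValueError(f"missing columns: {missing}")
            X = X[list(columns)]
            cols = list(columns)
        else:
            cols = list(X.columns)
        return X.to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    return X, columns if columns is not None else [f"x{i}" for i in range(X.shape[1])]


def fit_coral(X_s, y_s, X_t, lambda_reg: float | None = None,
              ridge_alpha: float | str = 1.0) -> CoralModel:
    """Two-stage CORAL fit: align source features to the target covariance,
    then ridge-regress the source response on the aligned features.

    Both domains are mean-centred by their own column means before
    alignment (the alignment itself is a pure covariance statement). No
    target response values are consumed.

    Parameters
    ----------
    lambda_reg:
        Covariance regulariser added to both covariance diagonals and used
        as the eigenvalue floor. Default: 1e-5 times the mean pooled
        covariance diagonal (relative regularisation).
    ridge_alpha:
        Ridge penalty on the standardised aligned features, or ``"cv"`` for
        5-fold cross-validated selection on the source.
    """
    Xs, cols_s = _as_matrix(X_s)
    Xt, cols_t = _as_matrix(X_t)
    if cols_s != cols_t:
        raise ValueError(f"source/target column mismatch: {cols_s} vs {cols_t}")
    y = np.asarray(y_s, dtype=float)
    if y.shape[0] != Xs.shape[0]:
        raise ValueError("y_s length does not match X_s")

    mu_s = Xs.mean(axis=0)
    mu_t = Xt.mean(axis=0)
    Xs_c = Xs - mu_s
    Xt_c = Xt - mu_t

    if lambda_reg is None:
        pooled_diag = 0.5 * (Xs_c.var(axis=0, ddof=1) + Xt_c.var(axis=0, ddof=1))
        lambda_reg = 1e-5 * float(pooled_diag.mean())
        lambda_reg = max(lambda_reg, 1e-12)

    C_S = estimate_covariance(Xs_c, lambda_reg)
    C_T = estimate_covariance(Xt_c, lambda_reg)
    A = coral_transform(C_S, C_T, eig_floor=lambda_reg)

    Z_s = Xs_c @ A
    scale = Z_s.std(axis=0, ddof=0)
    scale[scale == 0.0] = 1.0
    Z_s = Z_s / scale

    if ridge_alpha == "cv":
        reg = RidgeCV(alphas=np.logspace(-3, 3, 13), cv=5).fit(Z_s, y)
        alpha = float(reg.alpha_)
    else:
        alpha = float(ridge_alpha)
        reg = Ridge(alpha=alpha).fit(Z_s, y)

    return CoralModel(columns=cols_s, A=A, lambda_reg=float(lambda_reg),
                      mean_source=mu_s, mean_target=mu_t, scale=scale,
                      ridge_alpha=alpha, ridge_coef=np.asarray(reg.coef_),
                      ridge_intercept=float(reg.intercept_))


def predict_coral(model: CoralModel, X_t) -> np.ndarray:
    """Predict target segments with a fitted CORAL model.

    Target features are centred by the stored target means and scaled with
    the source-side standardisation; they live in the aligned space by
    construction (the source was transformed *toward* the target), so no
    further transform is applied.
    """
    Xt, _ = _as_matrix(X_t, columns=model.columns)
    Z_t = (Xt - model.mean_target) / model.scale
    return Z_t @ model.ridge_coef + model.ridge_intercept
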