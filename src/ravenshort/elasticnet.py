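"""Elastic-net linear regression by cyclic coordinate descent.

Objective (glmnet convention, so that penalty weights in the low single
digits are meaningful against an unstandardized sum-score outcome):

    (1/(2n)) * sum_i (y_i - b0 - x_i . beta)^2
        + lambda * ( alpha * ||beta||_1  +  (1 - alpha)/2 * ||beta||_2^2 )

The intercept is never penalized. By default predictors are standardized
internally to unit variance (population 1/n convention, again matching
glmnet) and coefficients are reported back on the original scale; the
outcome is only centred, never scaled. The per-coordinate update is the
soft-thresholding rule

    beta_j <- S(rho_j, lambda*alpha) / (v_j + lambda*(1 - alpha)),

with S the soft-threshold operator, rho_j the partial covariance of
predictor j with the current residual and v_j the predictor's (1/n)
squared norm. Sweeps use precomputed Gram quantities, so one full cycle is
O(p^2) regardless of n. The objective is non-increasing across sweeps; the
recorded trace makes that checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .items import is_item_label, sort_items


@dataclass(frozen=True)
class PenaltySpec:
    """One point of the penalty surface: overall weight λ and mixing α (1 = lasso, 0 = ridge)."""

    lambda_: float
    alpha: float

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ConfigurationError(f"lambda must be non-negative, got {self.lambda_}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must lie in [0, 1], got {self.alpha}")

    def to_dict(self) -> dict:
        return {"lambda": self.lambda_, "alpha": self.alpha}


@dataclass
class ElasticNetFit:
    """Solution at one (λ, α): intercept and per-predictor coefficients on the original scale."""

    intercept: float
    coefficients: pd.Series
    penalty: PenaltySpec
    n_iterations: int
    converged: bool
    objective_value: float
    objective_trace: np.ndarray  # working-scale objective after each sweep

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients.to_numpy()

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "penalty": self.penalty.to_dict(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "objective_value": self.objective_value,
        }


def soft_threshold(z: Union[float, np.ndarray], gamma: float):
    """Soft-thresholding operator ``sign(z) * max(|z| - gamma, 0)`` (gamma >= 0)."""
    if gamma < 0:
        raise ConfigurationError(f"soft_threshold requires gamma >= 0, got {gamma}")
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.maximum(np.abs(z) - gamma, 0.0)
    return float(out) if out.ndim == 0 else out


def _gram_objective(beta, G, c, y_var, lam, alpha):
    quad = 0.5 * (y_var - 2.0 * (c @ beta) + beta @ (G @ beta))
    pen = lam * (alpha * np.abs(beta).sum() + 0.5 * (1.0 - alpha) * (beta @ beta))
    return quad + pen


def _coordinate_descent(
    G: np.ndarray,
    c: np.ndarray,
    y_var: float,
    lam: float,
    alpha: float,
    beta0: Optional[np.ndarray],
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, int, bool, np.ndarray]:
    """Cyclic coordinate descent on Gram quantities G = X'X/n, c = X'y/n."""
    p = len(c)
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    diag = np.diag(G).copy()
    active = diag > 0  # zero-variance predictors stay at exactly 0
    beta[~active] = 0.0
    Gb = G @ beta
    l1 = lam * alpha
    l2 = lam * (1.0 - alpha)
    trace = [_gram_objective(beta, G, c, y_var, lam, alpha)]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            if not active[j]:
                continue
            rho = c[j] - Gb[j] + diag[j] * beta[j]
            new = soft_threshold(rho, l1) / (diag[j] + l2)
            delta = new - beta[j]
            if delta != 0.0:
                beta[j] = new
                Gb += G[:, j] * delta
                ad = abs(delta)
                if ad > max_delta:
                    max_delta = ad
        trace.append(_gram_objective(beta, G, c, y_var, lam, alpha))
        if max_delta < tol:
            converged = True
            break
    return beta, n_iter, converged, np.asarray(trace)


def _as_matrix(X) -> Tuple[np.ndarray, List[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise DataError(f"X must be 2-dimensional, got shape {arr.shape}")
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def fit_elastic_net(
    X,
    y,
    penalty: PenaltySpec,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    standardize: bool = True,
) -> ElasticNetFit:
    """Fit the elastic net for one penalty by cyclic coordinate descent.

    ``X`` is an (n, p) array or DataFrame of predictors (items as columns),
    ``y`` the outcome (the full-test sum score in the short-form pipeline).
    With ``standardize=True`` (default) predictors are scaled to unit 1/n
    variance internally and coefficients mapped back to the original scale;
    zero-variance predictors always receive coefficient exactly 0.
    """
    Xa, labels = _as_matrix(X)
    ya = np.asarray(y, dtype=float).ravel()
    n, p = Xa.shape
    if n < 2:
        raise DataError(f"need at least 2 observations, got {n}")
    if len(ya) != n:
        raise DataError(f"X has {n} rows but y has {len(ya)}")
    if not (np.isfinite(Xa).all() and np.isfinite(ya).all()):
        raise DataError("X and y must be finite")

    x_mean = Xa.mean(axis=0)
    y_mean = ya.mean()
    Xc = Xa - x_mean
    yc = ya - y_mean
    sd = np.sqrt((Xc**2).mean(axis=0))
    nonzero = sd > 1e-12
    if standardize:
        Xw = np.where(nonzero, Xc / np.where(nonzero, sd, 1.0), 0.0)
    else:
        Xw = np.where(nonzero, Xc, 0.0)

    G = Xw.T @ Xw / n
    c = Xw.T @ yc / n
    y_var = float(yc @ yc) / n

    beta_w, n_iter, converged, trace = _coordinate_descent(
        G, c, y_var, penalty.lambda_, penalty.alpha, None, tol, max_iter
    )
    beta = np.where(nonzero, beta_w / np.where(nonzero, sd, 1.0), 0.0) if standardize else beta_w
    intercept = float(y_mean - x_mean @ beta)
    return ElasticNetFit(
        intercept=intercept,
        coefficients=pd.Series(beta, index=labels),
        penalty=penalty,
        n_iterations=n_iter,
        converged=converged,
        objective_value=float(trace[-1]),
        objective_trace=trace,
    )


def active_set(fit: ElasticNetFit, threshold: float = 0.0) -> List[str]:
    """Labels of predictors with |coefficient| > threshold, in canonical item order.

    Falls back to input column order when the labels are not all item labels.
    """
    coefs = fit.coefficients
    chosen = [str(l) for l in coefs.index[np.abs(coefs.to_numpy()) > threshold]]
    if chosen and all(is_item_label(l) for l in chosen):
        return sort_items(chosen)
    return chosen
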