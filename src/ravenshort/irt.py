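"""Two-parameter logistic IRT baseline: marginal-maximum-likelihood EM fit,
item information, information-based item selection and method comparison.

The model is the same 2PL used by the synthetic generator:
``P_i(θ) = σ(a_i (θ - b_i))``. Estimation is Bock–Aitkin EM: abilities are
integrated out against a fixed Normal(0, 1) prior (which also identifies the
scale) on a Gauss–Hermite quadrature grid; the M-step maximizes each item's
expected complete-data log-likelihood by Newton steps with step halving, so
the marginal log-likelihood is non-decreasing across EM iterations.

Item selection mirrors a classical short-form recipe: rank items by expected
Fisher information under the ability prior, ``E_θ[a_i² P_i(θ) (1-P_i(θ))]``,
and keep the top *k*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import ItemResponseMatrix
from .errors import ConfigurationError, DataError
from .evaluation import cronbach_alpha, validate_form
from .items import is_item_label, sort_items


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.exp(_log_sigmoid(z))


@dataclass
class TwoPLModel:
    """Fitted 2PL item parameters plus the quadrature grid and likelihood trace."""

    a: pd.Series  # discrimination per item (NaN for inestimable items)
    b: pd.Series  # difficulty per item
    theta_nodes: np.ndarray
    theta_weights: np.ndarray
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    n_iterations: int
    converged: bool
    inestimable: List[str] = field(default_factory=list)

    @property
    def estimable_items(self) -> List[str]:
        return [l for l in self.a.index if l not in self.inestimable]

    def probability(self, item: str, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return _sigmoid(self.a[item] * (theta - self.b[item]))

    def to_dict(self) -> dict:
        return {
            "a": {k: (None if np.isnan(v) else float(v)) for k, v in self.a.items()},
            "b": {k: (None if np.isnan(v) else float(v)) for k, v in self.b.items()},
            "log_likelihood": self.log_likelihood,
            "log_likelihood_trace": [float(v) for v in self.log_likelihood_trace],
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "inestimable": list(self.inestimable),
        }


def _marginal_loglik(X, a, d, theta, logw):
    z = theta[None, :] * a[:, None] + d[:, None]  # (items, q)
    logp = _log_sigmoid(z)
    logq = _log_sigmoid(-z)
    A = X @ logp + (1 - X) @ logq  # (persons, q)
    A = A + logw[None, :]
    m = A.max(axis=1, keepdims=True)
    ll_person = m[:, 0] + np.log(np.exp(A - m).sum(axis=1))
    return float(ll_person.sum()), A, m


def _expected_counts(X, A, m):
    post = np.exp(A - m)
    post /= post.sum(axis=1, keepdims=True)  # (persons, q)
    nq = post.sum(axis=0)  # (q,)
    r = X.T @ post  # (items, q)
    return nq, r


def _item_Q(a, d, theta, nq, r):
    z = theta[None, :] * a[:, None] + d[:, None]
    return (r * _log_sigmoid(z) + (nq[None, :] - r) * _log_sigmoid(-z)).sum(axis=1)


def _newton_mstep(a, d, theta, nq, r, n_steps=10, update_a=True):
    """Vectorized per-item Newton maximization of the expected log-likelihood.

    Step halving guarantees no item's criterion decreases, which preserves
    the EM monotonicity of the marginal likelihood. With ``update_a=False``
    only the intercepts d move (used by the equal-discrimination fit).
    """
    a = a.copy()
    d = d.copy()
    for _ in range(n_steps):
        z = theta[None, :] * a[:, None] + d[:, None]
        e = _sigmoid(z)
        resid = r - nq[None, :] * e  # (items, q)
        ga = resid @ theta
        gd = resid.sum(axis=1)
        w = nq[None, :] * e * (1.0 - e)
        haa = w @ (theta**2)
        had = w @ theta
        hdd = w.sum(axis=1)
        if update_a:
            det = haa * hdd - had**2
            det = np.where(det < 1e-12, 1e-12, det)
            step_a = (hdd * ga - had * gd) / det
            step_d = (haa * gd - had * ga) / det
        else:
            step_a = np.zeros_like(a)
            step_d = gd / np.maximum(hdd, 1e-12)
        if max(np.abs(step_a).max(initial=0), np.abs(step_d).max(initial=0)) < 1e-10:
            break
        q_old = _item_Q(a, d, theta, nq, r)
        scale = np.ones_like(a)
        for _half in range(30):
            q_new = _item_Q(a + scale * step_a, d + scale * step_d, theta, nq, r)
            worse = q_new < q_old - 1e-12
            if not worse.any():
                break
            scale[worse] *= 0.5
        else:
            scale[worse] = 0.0
        a = a + scale * step_a
        d = d + scale * step_d
    return a, d


def fit_2pl(
    matrix: ItemResponseMatrix,
    n_quadrature: int = 21,
    tol: float = 1e-4,
    max_iter: int = 500,
    equal_discrimination: bool = False,
) -> TwoPLModel:
    """Fit the 2PL by marginal-maximum-likelihood EM.

    Items answered identically by everyone are flagged inestimable (their
    parameters are NaN) and skipped. ``equal_discrimination=True`` constrains
    all discriminations to a common value (a Rasch-type fit on the logit
    scale). Convergence: absolute change in marginal log-likelihood < tol.
    """
    items = matrix.administered_items
    if len(items) < 2:
        raise DataError("2PL fit needs at least 2 items")
    X_all = matrix.complete_values().astype(float)
    phat = X_all.mean(axis=0)
    estimable = [(j, l) for j, l in enumerate(items) if 0.0 < phat[j] < 1.0]
    inestimable = [l for j, l in enumerate(items) if not 0.0 < phat[j] < 1.0]
    if len(estimable) < 2:
        raise DataError("fewer than 2 estimable items")
    cols = [j for j, _ in estimable]
    X = X_all[:, cols]
    p0 = np.clip(phat[cols], 0.01, 0.99)

    gh_nodes, gh_weights = np.polynomial.hermite.hermgauss(n_quadrature)
    theta = np.sqrt(2.0) * gh_nodes  # Normal(0,1) prior
    logw = np.log(gh_weights / np.sqrt(np.pi))

    a = np.ones(len(cols))
    d = np.log(p0 / (1.0 - p0))
    ll, A, m = _marginal_loglik(X, a, d, theta, logw)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nq, r = _expected_counts(X, A, m)
        if equal_discrimination:
            for _cycle in range(3):
                # d-step at fixed common a, then 1-D Newton on the shared a
                _, d = _newton_mstep(a, d, theta, nq, r, n_steps=3, update_a=False)
                z = theta[None, :] * a[:, None] + d[:, None]
                e = _sigmoid(z)
                g = float(((r - nq[None, :] * e) @ theta).sum())
                h = float((nq[None, :] * e * (1 - e) @ (theta**2)).sum())
                step = g / max(h, 1e-12)
                q_old = _item_Q(a, d, theta, nq, r).sum()
                scale = 1.0
                for _half in range(30):
                    if _item_Q(a + scale * step, d, theta, nq, r).sum() >= q_old - 1e-12:
                        break
                    scale *= 0.5
                else:
                    scale = 0.0
                a = a + scale * step
        else:
            a, d = _newton_mstep(a, d, theta, nq, r)
        a = np.maximum(a, 1e-3)  # keep discriminations positive
        ll_new, A, m = _marginal_loglik(X, a, d, theta, logw)
        trace.append(ll_new)
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    a_full = pd.Series(np.nan, index=items)
    b_full = pd.Series(np.nan, index=items)
    a_full.iloc[cols] = a
    b_full.iloc[cols] = -d / a
    return TwoPLModel(
        a=a_full,
        b=b_full,
        theta_nodes=theta,
        theta_weights=np.exp(logw),
        log_likelihood=ll,
        log_likelihood_trace=np.asarray(trace),
        n_iterations=it,
        converged=converged,
        inestimable=inestimable,
    )


def item_information(model: TwoPLModel, item: str, theta) -> np.ndarray:
    """Fisher information ``a² P(θ) (1 - P(θ))`` of one item at ability θ."""
    if item in model.inestimable:
        raise DataError(f"item {item!r} is inestimable")
    p = model.probability(item, theta)
    out = model.a[item] ** 2 * p * (1.0 - p)
    return float(out) if np.ndim(out) == 0 else out


def expected_information(
    model: TwoPLModel,
    theta: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> pd.Series:
    """Prior-weighted expected information per estimable item.

    Defaults to the model's own quadrature grid (Normal(0,1) prior); pass an
    explicit ``theta``/``weights`` pair for alternatives such as information
    at θ = 0 only.
    """
    theta = model.theta_nodes if theta is None else np.asarray(theta, dtype=float)
    weights = model.theta_weights if weights is None else np.asarray(weights, dtype=float)
    if theta.shape != weights.shape:
        raise ConfigurationError("theta and weights must have the same shape")
    out = {}
    for item in model.estimable_items:
        out[item] = float(weights @ item_information(model, item, theta))
    return pd.Series(out)


def select_items_by_information(
    model: TwoPLModel,
    k: int = 15,
    theta: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
) -> List[str]:
    """The k items with the largest expected information, in canonical order."""
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    info = expected_information(model, theta, weights)
    if k > len(info):
        raise ConfigurationError(f"k={k} exceeds the {len(info)} estimable items")
    top = info.sort_values(ascending=False).index[:k]
    labels = list(top)
    if all(is_item_label(l) for l in labels):
        return sort_items(labels)
    return labels


@dataclass
class MethodComparison:
    """Validation correlation and Cronbach's alpha per selection method."""

    table: pd.DataFrame  # columns: method, r, alpha, length

    def to_dict(self) -> dict:
        return {"table": self.table.to_dict(orient="records")}


def compare_methods(
    forms_by_method: Mapping[str, Sequence[str]],
    validation_matrix: ItemResponseMatrix,
    full_items: Optional[Sequence[str]] = None,
) -> MethodComparison:
    """Score each method's form on the same validation matrix."""
    rows = []
    for method, form in forms_by_method.items():
        if not form:
            raise DataError(f"method {method!r} supplied an empty form")
        r = validate_form(form, validation_matrix, full_items)
        alpha = cronbach_alpha(validation_matrix, form).cronbach_alpha
        rows.append({"method": method, "r": r, "alpha": alpha, "length": len(form)})
    return MethodComparison(table=pd.DataFrame(rows, columns=["method", "r", "alpha", "length"]))
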