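"""Weighted logistic regression and closed-form linear Shapley attribution.

The classifier is an L2-regularized logistic regression whose log-likelihood
terms may carry per-case weights (the locally weighted fit). Its decision
function is linear, so Shapley values under the feature-independence
(interventional) convention have the closed form

    phi_ij = beta_j * (x_ij - mu_j)

where ``mu`` is the per-feature mean of the background data. Attribution is
on the log-odds scale. Averaging |phi| over the explained rows gives the
per-feature importance used for recommendation; ties are broken by the
pool's canonical column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .exceptions import DegenerateTrainingError, ValidationError

#: frozen fit defaults: L2 penalty, C=1, deterministic quasi-Newton solver
DEFAULT_C = 1.0
_SOLVER = "lbfgs"
_TOL = 1e-6
_MAX_ITER = 1000


@dataclass(frozen=True)
class LinearClassifier:
    """A fitted linear log-odds model: f(x) = intercept + beta . x."""

    beta: np.ndarray
    intercept: float
    feature_names: tuple[str, ...] | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.beta.shape[0]:
            raise ValidationError(
                f"expected {self.beta.shape[0]} columns, got {X.shape}"
            )
        return self.intercept + X @ self.beta


@dataclass(frozen=True)
class ImportanceRanking:
    """Mean-|phi| importance per feature and the induced descending order."""

    importance: dict[str, float]
    order: tuple[str, ...]

    def top(self, among: list[str] | None = None) -> str | None:
        """Highest-ranked feature, optionally restricted to ``among``."""
        pool = set(among) if among is not None else None
        for name in self.order:
            if pool is None or name in pool:
                return name
        return None


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    C: float = DEFAULT_C,
    feature_names: list[str] | None = None,
) -> LinearClassifier:
    """Fit the (optionally sample-weighted) L2 logistic regression.

    Minimizes ``(1/C) * 0.5*||beta||^2 + sum_i w_i * logloss(y_i, f(x_i))``
    with an unpenalized intercept; ``w=None`` means unit weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite values in X")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateTrainingError(
            f"training data contains a single outcome class ({classes.tolist()})"
        )
    if w is not None:
        w = np.asarray(w, dtype=float)
        if w.shape[0] != X.shape[0]:
            raise ValidationError("weight vector length does not match X")
        if not np.isfinite(w).all() or (w <= 0).any():
            raise ValidationError("weights must be positive and finite")
    # ridge (L2) penalty is the estimator default; C is the inverse strength
    model = LogisticRegression(C=C, solver=_SOLVER, tol=_TOL, max_iter=_MAX_ITER)
    model.fit(X, y, sample_weight=w)
    return LinearClassifier(
        beta=model.coef_[0].copy(),
        intercept=float(model.intercept_[0]),
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def background_mean(X: np.ndarray) -> np.ndarray:
    """Unweighted per-feature mean of the reference data (the SHAP background)."""
    return np.asarray(X, dtype=float).mean(axis=0)


def linear_shap(
    model: LinearClassifier, X: np.ndarray, background: np.ndarray
) -> np.ndarray:
    """Exact Shapley attributions of the linear model on the log-odds scale.

    Under feature independence the attribution of feature j for row i is
    ``beta_j * (x_ij - mu_j)``; rows sum to ``f(x_i) - f(mu)`` (local accuracy).
    """
    X = np.asarray(X, dtype=float)
    mu = np.asarray(background, dtype=float)
    if mu.shape[0] != model.beta.shape[0] or X.shape[1] != model.beta.shape[0]:
        raise ValidationError("background/X width does not match the model")
    return (X - mu) * model.beta


def mean_abs_importance(
    phi: np.ndarray, feature_names: list[str]
) -> ImportanceRanking:
    """Average |phi| per feature; order descending with canonical tie-break."""
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or phi.shape[0] == 0:
        raise ValidationError("attribution matrix must be non-empty and 2-D")
    if phi.shape[1] != len(feature_names):
        raise ValidationError("attribution width does not match feature names")
    scores = np.abs(phi).mean(axis=0)
    # stable sort on -score preserves canonical column order among ties
    order = [feature_names[j] for j in np.argsort(-scores, kind="stable")]
    return ImportanceRanking(
        importance={name: float(s) for name, s in zip(feature_names, scores)},
        order=tuple(order),
    )


def predict_prob(model: LinearClassifier, X: np.ndarray) -> np.ndarray:
    """Predicted probability of the positive class, sigmoid of the log-odds."""
    return expit(model.decision_function(X))
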