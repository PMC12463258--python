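"""Reference next-feature selectors used for comparison.

Three selectors rank the candidate (missing) features of a partition:

* sequential forward selection — score each candidate by the cross-validated
  accuracy of a classifier on initial + candidate;
* L1-penalized selection — fit a lasso-penalized logistic regression on all
  features and rank candidates by |coefficient|;
* explanation-guided imputation (simplified) — find the query's nearest
  known cases, impute the missing features from those neighbors to build
  synthetic completions, and rank candidates by the mean |attribution| of a
  single unweighted global model on those completions. The original method
  it emulates uses a boosted-tree model on much larger data; this logistic
  variant supports qualitative comparison only.

The first two are population-level (one ranking per partition); the third is
individualized (one ranking per patient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .case_store import CaseTable, FeaturePartition, PatientQuery, identify_missing
from .exceptions import ConfigurationError
from .local_model import background_mean, fit_weighted_logistic, linear_shap
from .similarity import euclidean_distance


@dataclass(frozen=True)
class SelectorResult:
    """Candidate features ordered best-first with their scores."""

    order: tuple[str, ...]
    scores: dict[str, float]
    method: str

    @property
    def top(self) -> str | None:
        return self.order[0] if self.order else None


def _rank_candidates(
    candidates: list[str], scores: dict[str, float], canonical: list[str], method: str
) -> SelectorResult:
    # stable sort on -score; canonical column order breaks ties
    in_order = [f for f in canonical if f in set(candidates)]
    ranked = sorted(in_order, key=lambda f: -scores[f])
    return SelectorResult(order=tuple(ranked), scores=dict(scores), method=method)


def sfs_select(
    table: CaseTable,
    partition: FeaturePartition,
    folds: int = 5,
    seed: int = 0,
) -> SelectorResult:
    """One forward-selection step: cross-validated accuracy per candidate."""
    scores: dict[str, float] = {}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for cand in partition.candidate:
        cols = partition.initial + [cand]
        model = LogisticRegression(C=1.0, solver="lbfgs", tol=1e-6, max_iter=1000)
        scores[cand] = float(
            cross_val_score(
                model, table.columns(cols), table.y, cv=cv, scoring="accuracy"
            ).mean()
        )
    return _rank_candidates(
        partition.candidate, scores, table.feature_names, method="sfs"
    )


def lasso_select(
    table: CaseTable,
    partition: FeaturePartition,
    penalty: float | None = None,
    seed: int = 0,
) -> SelectorResult:
    """Rank candidates by |coefficient| of an L1-penalized logistic fit.

    ``penalty`` is the inverse regularization strength C; when omitted it is
    chosen by 5-fold cross-validation.
    """
    X = table.X
    if penalty is None:
        model = LogisticRegressionCV(
            l1_ratios=[1.0],
            solver="liblinear",
            Cs=np.logspace(-2, 3, 11),
            cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
            scoring="accuracy",
            max_iter=1000,
        )
    else:
        if penalty <= 0:
            raise ConfigurationError("penalty must be positive")
        model = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", C=penalty, max_iter=1000
        )
    model.fit(X, table.y)
    coefs = dict(zip(table.feature_names, np.abs(model.coef_[0])))
    scores = {f: float(coefs[f]) for f in partition.candidate}
    if all(v == 0.0 for v in scores.values()):
        # fully shrunk fit carries no ordering information
        import logging

        logging.getLogger(__name__).warning(
            "lasso shrank every candidate coefficient to zero; canonical order used"
        )
    return _rank_candidates(
        partition.candidate, scores, table.feature_names, method="lasso"
    )


def eguided_select(
    table: CaseTable,
    query: PatientQuery,
    k_similar: int = 100,
    n_imputations: int = 10,
    seed: int = 0,
) -> SelectorResult:
    """Simplified explanation-guided selection via neighbor imputation.

    Draws each missing feature independently from the query's ``k_similar``
    nearest cases to form ``n_imputations`` synthetic completions, then
    ranks candidates by mean |attribution| of one unweighted global model
    evaluated on those completions.
    """
    if n_imputations < 1:
        raise ConfigurationError("n_imputations must be at least 1")
    if k_similar > table.n:
        raise ConfigurationError(
            f"k_similar={k_similar} exceeds the pool size {table.n}"
        )
    partition = identify_missing(query, table)
    d = euclidean_distance(query, table, partition.initial)
    neighbor_idx = np.argsort(d, kind="stable")[:k_similar]

    rng = np.random.default_rng(seed)
    samples = np.empty((n_imputations, table.p))
    for j, name in enumerate(table.feature_names):
        if name in query.observed:
            samples[:, j] = query.observed[name]
        else:
            pool = table.X[neighbor_idx, j]
            samples[:, j] = rng.choice(pool, size=n_imputations, replace=True)

    model = fit_weighted_logistic(table.X, table.y, feature_names=table.feature_names)
    phi = linear_shap(model, samples, background_mean(table.X))
    mean_abs = np.abs(phi).mean(axis=0)
    scores = {
        f: float(mean_abs[table.feature_names.index(f)]) for f in partition.candidate
    }
    return _rank_candidates(
        partition.candidate, scores, table.feature_names, method="eguided"
    )
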