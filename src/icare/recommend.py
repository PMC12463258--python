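"""Next-feature recommendation, individualized or population-wide.

The individualized path weighs every known case by its inverse distance to
the incoming patient (over the patient's observed features), fits the
weighted logistic regression on *all* pool features, attributes it with the
linear Shapley explainer over the whole pool, and recommends the
highest-ranked feature the patient is missing. The global path is the same
pipeline with unit weights, producing one recommendation shared by every
patient with the same missing set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .case_store import CaseTable, FeaturePartition, PatientQuery, identify_missing
from .local_model import (
    ImportanceRanking,
    background_mean,
    fit_weighted_logistic,
    linear_shap,
    mean_abs_importance,
    predict_prob,  # noqa: F401  (re-exported for CLI convenience)
)
from .similarity import case_weights


@dataclass(frozen=True)
class RecommendationResult:
    """Full importance ranking plus the chosen missing feature (if any)."""

    ranking: ImportanceRanking
    recommended: str | None
    mode: str


def _rank_features(table: CaseTable, weights) -> ImportanceRanking:
    model = fit_weighted_logistic(
        table.X, table.y, w=weights, feature_names=table.feature_names
    )
    phi = linear_shap(model, table.X, background_mean(table.X))
    return mean_abs_importance(phi, table.feature_names)


def icare_recommend(table: CaseTable, query: PatientQuery) -> RecommendationResult:
    """Individualized recommendation for one patient.

    Ranks all pool features by mean-|phi| of the patient-weighted model,
    then filters to the features the patient is missing.
    """
    partition = identify_missing(query, table)
    w = case_weights(query, table, partition.initial)
    ranking = _rank_features(table, w)
    recommended = ranking.top(partition.candidate) if partition.candidate else None
    return RecommendationResult(ranking=ranking, recommended=recommended, mode="icare")


def global_recommend(
    table: CaseTable, partition: FeaturePartition
) -> RecommendationResult:
    """Population-wide recommendation: the unweighted variant of the pipeline."""
    ranking = _rank_features(table, None)
    recommended = ranking.top(partition.candidate) if partition.candidate else None
    return RecommendationResult(ranking=ranking, recommended=recommended, mode="global")
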