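"""Four-arm evaluation harness for feature-recommendation strategies.

Protocol per iteration: split the table 80/20 into a pool of known cases and
test patients; strip test patients down to the initial features (chosen once
as the k *least* important features of a global fit); produce one population
recommendation (Global arms) and one per-patient recommendation
(individualized arms); reveal each patient's true value of their recommended
feature; fit the inference model on pool columns initial + recommended —
plain for the non-LW arms, similarity-weighted per patient for the LW arms —
and predict that single patient. Accuracy is the fraction of patients
correct at probability threshold 0.5; AUC is the rank statistic of the
pooled per-patient probabilities against the true labels. Metrics are
averaged over the repeated splits; a ceiling model trained on all features
provides the upper reference per iteration.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .case_store import CaseTable, FeaturePartition, PatientQuery
from .exceptions import ConfigurationError, DegenerateTrainingError
from .local_model import (
    background_mean,
    fit_weighted_logistic,
    linear_shap,
    mean_abs_importance,
    predict_prob,
)
from .recommend import global_recommend, icare_recommend
from .similarity import case_weights

logger = logging.getLogger(__name__)

#: evaluation arms: recommendation strategy x inference weighting
ARMS = ("global", "global_lw", "icare", "icare_lw")
#: offset between retried split seeds when a split lands single-class
_RESEED_STRIDE = 100_003


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings of one repeated-split experiment."""

    n_iterations: int = 100
    test_fraction: float = 0.2
    k_initial: int = 1
    arms: tuple[str, ...] = ARMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        unknown = set(self.arms) - set(ARMS)
        if unknown:
            raise ConfigurationError(f"unknown arms: {sorted(unknown)}")


@dataclass
class IterationArm:
    accuracy: float
    auc: float
    tally: Counter


@dataclass
class IterationResult:
    arms: dict[str, IterationArm]
    ceiling_accuracy: float
    ceiling_auc: float


@dataclass
class ArmResult:
    """Per-iteration metric vectors and recommendation tallies for one arm."""

    accuracy: np.ndarray
    auc: np.ndarray
    tally: Counter

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracy.mean())

    @property
    def mean_auc(self) -> float:
        return float(self.auc.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracy.std(ddof=1)) if self.accuracy.size > 1 else 0.0

    @property
    def sd_auc(self) -> float:
        return float(self.auc.std(ddof=1)) if self.auc.size > 1 else 0.0


@dataclass
class ExperimentResult:
    """Aggregate of one experiment: arm metrics, tallies and the ceiling."""

    arms: dict[str, ArmResult]
    ceiling_accuracy: np.ndarray
    ceiling_auc: np.ndarray
    partition: FeaturePartition
    config: ExperimentConfig

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, arm in self.arms.items():
            rows.append(
                {
                    "arm": name,
                    "mean_accuracy": arm.mean_accuracy,
                    "sd_accuracy": arm.sd_accuracy,
                    "mean_auc": arm.mean_auc,
                    "sd_auc": arm.sd_auc,
                }
            )
        rows.append(
            {
                "arm": "ceiling",
                "mean_accuracy": float(self.ceiling_accuracy.mean()),
                "sd_accuracy": float(self.ceiling_accuracy.std(ddof=1))
                if self.ceiling_accuracy.size > 1
                else 0.0,
                "mean_auc": float(self.ceiling_auc.mean()),
                "sd_auc": float(self.ceiling_auc.std(ddof=1))
                if self.ceiling_auc.size > 1
                else 0.0,
            }
        )
        return pd.DataFrame(rows)

    def per_iteration_frame(self) -> pd.DataFrame:
        data = {"iteration": np.arange(self.config.n_iterations)}
        for name, arm in self.arms.items():
            data[f"{name}_accuracy"] = arm.accuracy
            data[f"{name}_auc"] = arm.auc
        data["ceiling_accuracy"] = self.ceiling_accuracy
        data["ceiling_auc"] = self.ceiling_auc
        return pd.DataFrame(data)

    def tally_frame(self) -> pd.DataFrame:
        rows = []
        for name, arm in self.arms.items():
            total = sum(arm.tally.values())
            for feature, count in sorted(arm.tally.items()):
                rows.append(
                    {
                        "arm": name,
                        "feature": feature,
                        "count": count,
                        "fraction": count / total if total else np.nan,
                    }
                )
        return pd.DataFrame(rows, columns=["arm", "feature", "count", "fraction"])


def select_initial_features(table: CaseTable, k: int) -> FeaturePartition:
    """Choose the k LEAST important features (global ranking) as the initial set.

    Emulates the realistic situation where incoming patients arrive with the
    least informative measurements already taken.
    """
    if not (1 <= k < table.p):
        raise ConfigurationError(f"k must satisfy 1 <= k < {table.p}, got {k}")
    model = fit_weighted_logistic(table.X, table.y, feature_names=table.feature_names)
    phi = linear_shap(model, table.X, background_mean(table.X))
    ranking = mean_abs_importance(phi, table.feature_names)
    lowest = set(ranking.order[-k:])
    initial = [f for f in table.feature_names if f in lowest]
    candidate = [f for f in table.feature_names if f not in lowest]
    return FeaturePartition(initial=initial, candidate=candidate)


def _split(table: CaseTable, test_fraction: float, seed: int):
    """80/20-style split; re-draw (next seed) while the test side is single-class."""
    n_test = max(1, int(round(table.n * test_fraction)))
    salt = 0
    while True:
        rng = np.random.default_rng(seed + salt * _RESEED_STRIDE)
        perm = rng.permutation(table.n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        if np.unique(table.y[train_idx]).size < 2:
            raise DegenerateTrainingError(
                f"training split at seed {seed} contains a single class"
            )
        if np.unique(table.y[test_idx]).size == 2:
            return train_idx, test_idx
        salt += 1
        logger.info("single-class test split at seed %d; resampling (attempt %d)", seed, salt)
        if salt > 1000:
            raise DegenerateTrainingError("could not draw a two-class test split")


def _plain_inference(train: CaseTable, cols: list[str]):
    model = fit_weighted_logistic(
        train.columns(cols), train.y, feature_names=cols
    )
    return model


def run_iteration(
    table: CaseTable,
    partition: FeaturePartition,
    arms: tuple[str, ...] = ARMS,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> IterationResult:
    """One split-recommend-infer pass; returns per-arm accuracy, AUC and tallies."""
    train_idx, test_idx = _split(table, test_fraction, seed)
    train = table.subset_rows(train_idx)
    test_X = table.X[test_idx]
    test_y = table.y[test_idx]
    initial = partition.initial
    init_idx = table.column_indices(initial)

    need_global = any(a.startswith("global") for a in arms)
    need_icare = any(a.startswith("icare") for a in arms)

    global_rec = None
    if need_global:
        global_rec = global_recommend(train, partition).recommended

    icare_recs: list[str | None] = []
    if need_icare:
        for row in test_X:
            query = PatientQuery(dict(zip(initial, row[init_idx])))
            icare_recs.append(icare_recommend(train, query).recommended)

    # reusable plain inference models, keyed by recommended feature
    plain_cache: dict[str | None, object] = {}

    def plain_model(rec: str | None):
        if rec not in plain_cache:
            cols = initial + ([rec] if rec else [])
            plain_cache[rec] = _plain_inference(train, cols)
        return plain_cache[rec]

    def patient_prob(row: np.ndarray, rec: str | None, weighted: bool) -> float:
        cols = initial + ([rec] if rec else [])
        col_idx = table.column_indices(cols)
        xi = row[col_idx]
        if weighted:
            query = PatientQuery(dict(zip(cols, xi)))
            w = case_weights(query, train, cols)
            model = fit_weighted_logistic(train.columns(cols), train.y, w=w)
        else:
            model = plain_model(rec)
        return float(predict_prob(model, xi.reshape(1, -1))[0])

    out: dict[str, IterationArm] = {}
    for arm in arms:
        weighted = arm.endswith("_lw")
        if arm.startswith("global"):
            recs = [global_rec] * len(test_idx)
            tally = Counter([global_rec] if global_rec else [])
        else:
            recs = icare_recs
            tally = Counter(r for r in recs if r is not None)
        probs = np.array(
            [patient_prob(row, rec, weighted) for row, rec in zip(test_X, recs)]
        )
        acc = float(np.mean((probs > 0.5).astype(int) == test_y))
        auc = float(roc_auc_score(test_y, probs))
        out[arm] = IterationArm(accuracy=acc, auc=auc, tally=tally)

    ceiling = _plain_inference(train, list(table.feature_names))
    ceil_probs = predict_prob(ceiling, test_X)
    return IterationResult(
        arms=out,
        ceiling_accuracy=float(np.mean((ceil_probs > 0.5).astype(int) == test_y)),
        ceiling_auc=float(roc_auc_score(test_y, ceil_probs)),
    )


def run_experiment(
    table: CaseTable,
    config: ExperimentConfig,
    partition: FeaturePartition | None = None,
) -> ExperimentResult:
    """Repeat :func:`run_iteration` with seeds seed+0..seed+n-1 and aggregate."""
    if partition is None:
        partition = select_initial_features(table, config.k_initial)
    n = config.n_iterations
    acc = {a: np.empty(n) for a in config.arms}
    auc = {a: np.empty(n) for a in config.arms}
    tallies = {a: Counter() for a in config.arms}
    ceil_acc = np.empty(n)
    ceil_auc = np.empty(n)
    for i in range(n):
        res = run_iteration(
            table,
            partition,
            arms=config.arms,
            seed=config.seed + i,
            test_fraction=config.test_fraction,
        )
        for a in config.arms:
            acc[a][i] = res.arms[a].accuracy
            auc[a][i] = res.arms[a].auc
            tallies[a] += res.arms[a].tally
        ceil_acc[i] = res.ceiling_accuracy
        ceil_auc[i] = res.ceiling_auc
        logger.debug("iteration %d/%d done", i + 1, n)
    return ExperimentResult(
        arms={
            a: ArmResult(accuracy=acc[a], auc=auc[a], tally=tallies[a])
            for a in config.arms
        },
        ceiling_accuracy=ceil_acc,
        ceiling_auc=ceil_auc,
        partition=partition,
        config=config,
    )


def sweep_initial_features(
    table: CaseTable, config: ExperimentConfig, k_list: list[int]
) -> list[ExperimentResult]:
    """One experiment per initial-feature count, sharing split seeds across k."""
    results = []
    for k in k_list:
        cfg = ExperimentConfig(
            n_iterations=config.n_iterations,
            test_fraction=config.test_fraction,
            k_initial=k,
            arms=config.arms,
            seed=config.seed,
        )
        results.append(run_experiment(table, cfg))
    return results
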