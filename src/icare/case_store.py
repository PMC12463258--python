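"""Case pool loading, encoding and query handling.

The pool of known cases is a complete, labeled table of past patients: a
numeric feature matrix plus a binary outcome. Incoming patients arrive as
partial records (a subset of the pool's features); the first task of the
framework is to detect which features such a patient is missing.

Encoding conventions: binary string columns are mapped to {0, 1}
(Yes/No, Male/Female, Positive/Negative); continuous columns are min-max
scaled to [0, 1] by default so that Euclidean distances are not dominated
by wide-range columns. The scaling parameters learned from the pool are
retained and re-applied to every incoming query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UnknownFeatureError, ValidationError

# value -> {0,1} codings accepted for binary string columns
_BINARY_CODINGS: dict[str, int] = {
    "yes": 1, "no": 0,
    "male": 1, "female": 0,
    "positive": 1, "negative": 0,
    "true": 1, "false": 0,
}


@dataclass(frozen=True)
class FeatureScaler:
    """Per-column affine encoding learned from the pool.

    ``encode(v) = clip((v - low) / (high - low), 0, 1)`` when min-max scaling
    is enabled; identity otherwise. Constant columns encode to 0.
    """

    feature_names: tuple[str, ...]
    low: np.ndarray
    high: np.ndarray
    minmax: bool

    def encode(self, values: np.ndarray) -> np.ndarray:
        if not self.minmax:
            return np.asarray(values, dtype=float)
        span = self.high - self.low
        span = np.where(span == 0, 1.0, span)
        out = (np.asarray(values, dtype=float) - self.low) / span
        return np.clip(out, 0.0, 1.0)

    def encode_one(self, name: str, value: float) -> float:
        j = self.feature_names.index(name)
        if not self.minmax:
            return float(value)
        span = self.high[j] - self.low[j]
        if span == 0:
            return 0.0
        return float(np.clip((float(value) - self.low[j]) / span, 0.0, 1.0))

    def decode(self, encoded: np.ndarray) -> np.ndarray:
        if not self.minmax:
            return np.asarray(encoded, dtype=float)
        return np.asarray(encoded, dtype=float) * (self.high - self.low) + self.low


@dataclass
class CaseTable:
    """Complete labeled pool of known cases.

    Attributes
    ----------
    feature_names : list of str
        Canonical feature order (CSV header order); used for every ranking
        and tie-break downstream.
    X : ndarray, shape (n, p)
        Encoded feature matrix; entirely finite.
    y : ndarray, shape (n,)
        Binary outcome, values in {0, 1}.
    outcome_name : str
        Name of the outcome column in the source data.
    scaler : FeatureScaler
        Encoder applied to the pool, reused for incoming queries.
    """

    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    outcome_name: str = "class"
    scaler: FeatureScaler | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValidationError("duplicate feature names")
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise ValidationError("X shape does not match feature_names")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X and y lengths differ")
        if not np.isfinite(self.X).all():
            raise ValidationError("case pool contains missing or non-finite values")
        if not np.isin(self.y, (0, 1)).all():
            raise ValidationError("outcome must be binary {0, 1}")
        self.y = self.y.astype(int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_indices(self, names: list[str]) -> np.ndarray:
        try:
            return np.array([self.feature_names.index(f) for f in names], dtype=int)
        except ValueError as exc:
            raise UnknownFeatureError(str(exc)) from exc

    def columns(self, names: list[str]) -> np.ndarray:
        return self.X[:, self.column_indices(names)]

    def subset_rows(self, idx: np.ndarray) -> "CaseTable":
        return CaseTable(
            feature_names=list(self.feature_names),
            X=self.X[idx],
            y=self.y[idx],
            outcome_name=self.outcome_name,
            scaler=self.scaler,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=self.feature_names)
        frame[self.outcome_name] = self.y
        return frame


@dataclass(frozen=True)
class PatientQuery:
    """Partial feature record of an incoming patient (observed subset only)."""

    observed: dict[str, float]

    def __post_init__(self) -> None:
        if not self.observed:
            raise ValidationError("patient query must observe at least one feature")

    @property
    def feature_names(self) -> list[str]:
        return list(self.observed)

    def validate_against(self, table: CaseTable) -> None:
        unknown = set(self.observed) - set(table.feature_names)
        if unknown:
            raise UnknownFeatureError(f"unknown features in query: {sorted(unknown)}")
        if table.outcome_name in self.observed:
            raise ValidationError("query must not contain the outcome column")


@dataclass(frozen=True)
class FeaturePartition:
    """Split of the pool's features into observed (initial) and missing (candidate)."""

    initial: list[str]
    candidate: list[str]

    def __post_init__(self) -> None:
        if set(self.initial) & set(self.candidate):
            raise ValidationError("initial and candidate features overlap")


def _encode_binary_column(col: pd.Series) -> pd.Series:
    """Map a string-valued binary column to {0, 1} using the accepted codings."""
    values = col.astype(str).str.strip().str.lower()
    uniques = sorted(values.unique())
    if not all(u in _BINARY_CODINGS for u in uniques):
        raise ValidationError(
            f"column {col.name!r} is not binary-codable: values {uniques}"
        )
    return values.map(_BINARY_CODINGS).astype(float)


def load_cases(
    path,
    outcome_column: str = "class",
    scaling: str = "minmax",
) -> CaseTable:
    """Read a CSV of labeled cases into an encoded :class:`CaseTable`.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row; one column holds the binary outcome.
    outcome_column : str
        Name of the outcome column. Accepted codings: {0,1}, {Yes,No},
        {Positive,Negative}, {True,False}.
    scaling : {"minmax", "none"}
        Whether to min-max scale every feature column to [0, 1]. Binary
        columns containing both values are unchanged by min-max scaling.
    """
    if scaling not in ("minmax", "none"):
        raise ConfigurationError(f"unknown scaling mode {scaling!r}")
    frame = pd.read_csv(path)
    if outcome_column not in frame.columns:
        raise ConfigurationError(
            f"outcome column {outcome_column!r} not found in {list(frame.columns)}"
        )
    if frame.isna().any().any():
        raise ValidationError("case pool contains missing values; the pool must be complete")

    encoded = {}
    for name in frame.columns:
        col = frame[name]
        if col.dtype == object:
            encoded[name] = _encode_binary_column(col)
        else:
            encoded[name] = col.astype(float)
    enc = pd.DataFrame(encoded, columns=frame.columns)

    y = enc.pop(outcome_column).to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("outcome column is not binary {0, 1}")

    feature_names = list(enc.columns)
    raw = enc.to_numpy(dtype=float)
    low = raw.min(axis=0)
    high = raw.max(axis=0)
    scaler = FeatureScaler(
        feature_names=tuple(feature_names),
        low=low,
        high=high,
        minmax=(scaling == "minmax"),
    )
    return CaseTable(
        feature_names=feature_names,
        X=scaler.encode(raw),
        y=y,
        outcome_name=outcome_column,
        scaler=scaler,
    )


def encode_query(query: PatientQuery, table: CaseTable) -> PatientQuery:
    """Re-encode a raw-valued query with the pool's scaling parameters."""
    query.validate_against(table)
    if table.scaler is None:
        return query
    return PatientQuery(
        {name: table.scaler.encode_one(name, v) for name, v in query.observed.items()}
    )


def identify_missing(query: PatientQuery, table: CaseTable) -> FeaturePartition:
    """Partition the pool's features into the query's observed and missing sets.

    Both lists are returned in the pool's canonical column order.
    """
    query.validate_against(table)
    observed = set(query.observed)
    initial = [f for f in table.feature_names if f in observed]
    candidate = [f for f in table.feature_names if f not in observed]
    return FeaturePartition(initial=initial, candidate=candidate)
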