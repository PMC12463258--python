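"""Patient-to-pool similarity: Euclidean distances and inverse-distance weights.

Each known case receives a weight ``w_i = 1 / (d_i + 1e-9)`` where ``d_i`` is
the Euclidean distance between the case and the incoming patient over the
features the patient has observed. Nearer cases therefore dominate any
subsequent weighted fit; the epsilon keeps exact matches finite. Weights are
deliberately left unnormalized.
"""

from __future__ import annotations

import numpy as np

from .case_store import CaseTable, PatientQuery
from .exceptions import ConfigurationError, ValidationError

#: additive floor preventing division by zero for exact matches
DISTANCE_EPSILON = 1e-9


def euclidean_distance(
    query: PatientQuery, table: CaseTable, subset: list[str] | None = None
) -> np.ndarray:
    """Distance from every pool case to the query over ``subset`` features.

    ``subset`` defaults to all of the query's observed features; it must be
    non-empty and contained in both the query and the pool. The outcome
    column never participates.
    """
    if subset is None:
        subset = query.feature_names
    if len(subset) == 0:
        raise ConfigurationError("distance subset must be non-empty")
    missing = set(subset) - set(query.observed)
    if missing:
        raise ConfigurationError(f"subset features not observed by query: {sorted(missing)}")
    q = np.array([query.observed[f] for f in subset], dtype=float)
    diff = table.columns(list(subset)) - q
    return np.sqrt(np.sum(diff * diff, axis=1))


def weights_from_distances(d: np.ndarray) -> np.ndarray:
    """Convert distances to inverse-distance sample weights (unnormalized)."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValidationError("distances must be non-negative")
    return 1.0 / (d + DISTANCE_EPSILON)


def case_weights(
    query: PatientQuery, table: CaseTable, subset: list[str] | None = None
) -> np.ndarray:
    """Convenience composition: distances over ``subset`` then inverse weights."""
    return weights_from_distances(euclidean_distance(query, table, subset))
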