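"""Synthetic scenario generators for evaluating individualized recommendation.

Every scenario shares the same skeleton: an initial feature ``x`` uniform on
[0, 1], a balanced binary outcome independent of ``x``, and added features
whose predictive power is confined to stated intervals of ``x``. Inside a
predictive interval with a positive association the added feature is drawn
class-separably,

    A = 0.5 + s * U(margin, 0.5),   s = +1 if y = 1 else -1,

(a negative association flips ``s``); outside its intervals the feature is
pure Uniform(0, 1) noise. The five standard geometries:

1. feature_1 predictive on [0, 0.5), feature_2 on [0.5, 1] — complementary
   halves, the ideal case for individualized recommendation.
2. association sign flips *within* each feature's predictive half
   (feature_1: + on [0, 0.32), - on [0.32, 0.5); feature_2 mirrored), so no
   single pooled linear fit can exploit the feature fully while a locally
   weighted fit can. The flip point is off-center so a pooled fit keeps
   partial signal (best single-threshold accuracy ~2*0.32 inside the half).
3. feature_1 on [0, 0.7), feature_2 on [0.3, 1] — overlapping regions where
   both features are predictive for 0.3 < x < 0.7.
4. both features predictive on all of [0, 1] — identical in law, nothing to
   personalize.
5. feature_1 predictive on all of [0, 1] plus two pure-noise features — one
   dominant feature, nothing to personalize.

Column order is always x, feature_1, feature_2(, noise_...), outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .case_store import CaseTable
from .exceptions import ConfigurationError

#: (low, high, sign) intervals of the initial feature, per added feature
Region = tuple[float, float, int]

_STANDARD_REGIONS: dict[int, dict[str, list[Region]]] = {
    1: {"feature_1": [(0.0, 0.5, +1)], "feature_2": [(0.5, 1.0, +1)]},
    2: {
        "feature_1": [(0.0, 0.32, +1), (0.32, 0.5, -1)],
        "feature_2": [(0.5, 0.68, -1), (0.68, 1.0, +1)],
    },
    3: {"feature_1": [(0.0, 0.7, +1)], "feature_2": [(0.3, 1.0, +1)]},
    4: {"feature_1": [(0.0, 1.0, +1)], "feature_2": [(0.0, 1.0, +1)]},
    5: {"feature_1": [(0.0, 1.0, +1)]},
}
_STANDARD_NOISE: dict[int, int] = {1: 0, 2: 0, 3: 0, 4: 0, 5: 2}


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one synthetic scenario.

    ``regions`` maps each added-feature name to its list of
    (interval low, interval high, association sign) triples over the initial
    feature; intervals are half-open ``[low, high)`` except that ``x = 1``
    belongs to an interval ending at 1.
    """

    regions: dict[str, list[Region]]
    n_samples: int = 1000
    margin: float = 0.05
    n_pure_noise_features: int = 0
    seed: int = 0
    scenario_id: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 50:
            raise ConfigurationError("n_samples must be at least 50")
        if not (0.0 < self.margin < 0.5):
            raise ConfigurationError("margin must lie in (0, 0.5)")
        for name, regs in self.regions.items():
            for lo, hi, sign in regs:
                if not (0.0 <= lo < hi <= 1.0):
                    raise ConfigurationError(
                        f"invalid interval ({lo}, {hi}) for {name!r}"
                    )
                if sign not in (-1, +1):
                    raise ConfigurationError(f"association sign must be ±1, got {sign}")

    @classmethod
    def standard(
        cls,
        scenario_id: int,
        n_samples: int = 1000,
        margin: float = 0.05,
        seed: int = 0,
    ) -> "ScenarioSpec":
        """One of the five standard geometries described in the module docstring."""
        if scenario_id not in _STANDARD_REGIONS:
            raise ConfigurationError(f"scenario_id must be in 1..5, got {scenario_id}")
        return cls(
            regions={k: list(v) for k, v in _STANDARD_REGIONS[scenario_id].items()},
            n_samples=n_samples,
            margin=margin,
            n_pure_noise_features=_STANDARD_NOISE[scenario_id],
            seed=seed,
            scenario_id=scenario_id,
        )


def _in_interval(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    inside = (x >= lo) & (x < hi)
    if hi == 1.0:
        inside |= x == 1.0
    return inside


def generate(spec: ScenarioSpec, outcome_name: str = "class") -> CaseTable:
    """Draw one dataset from the scenario recipe (seeded, deterministic)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    x = rng.uniform(0.0, 1.0, size=n)
    y = rng.integers(0, 2, size=n)

    columns: dict[str, np.ndarray] = {"x": x}
    for name, regs in spec.regions.items():
        a = rng.uniform(0.0, 1.0, size=n)  # noise outside all predictive regions
        for lo, hi, sign in regs:
            inside = _in_interval(x, lo, hi)
            s = np.where(y == 1, sign, -sign)
            offset = rng.uniform(spec.margin, 0.5, size=n)
            a = np.where(inside, 0.5 + s * offset, a)
        columns[name] = a
    for k in range(spec.n_pure_noise_features):
        columns[f"noise_{k + 1}"] = rng.uniform(0.0, 1.0, size=n)

    names = list(columns)
    X = np.column_stack([columns[c] for c in names])
    return CaseTable(feature_names=names, X=X, y=y, outcome_name=outcome_name)


def generate_timing(
    n_samples: int = 500,
    n_features: int = 100,
    seed: int = 0,
    outcome_name: str = "class",
) -> CaseTable:
    """Pure-noise benchmark table: i.i.d. Uniform(0,1) features, balanced label."""
    if n_features < 1:
        raise ConfigurationError("n_features must be at least 1")
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n_samples, n_features))
    y = rng.integers(0, 2, size=n_samples)
    names = [f"feature_{j + 1}" for j in range(n_features)]
    return CaseTable(feature_names=names, X=X, y=y, outcome_name=outcome_name)
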