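"""Pairwise arm contrasts with Holm-corrected significance.

The evaluation harness produces per-iteration accuracy and AUC vectors for
each arm; arms sharing split seeds are compared with a paired t-test by
default (an unpaired variant is available). Because each report tests four
contrasts on two metrics, the eight raw p-values of one table form the
family for the step-down Holm adjustment, which controls the familywise
error rate without the full conservatism of Bonferroni.

Degenerate-variance conventions: identical vectors give p = 1 (no signal);
a constant non-zero paired difference gives p = 0 (the difference is
deterministic at the observed resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .evaluate import ExperimentResult
from .exceptions import ConfigurationError, ValidationError

#: the four contrasts of a standard report, as (name, arm_a, arm_b)
STANDARD_CONTRASTS = (
    ("icare_vs_global", "icare", "global"),
    ("icare_lw_vs_global_lw", "icare_lw", "global_lw"),
    ("icare_vs_icare_lw", "icare", "icare_lw"),
    ("global_vs_global_lw", "global", "global_lw"),
)


def star_code(p: float) -> str:
    """Significance stars: *** <0.001, ** <0.01, * <0.05, blank otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def contrast(
    a: np.ndarray, b: np.ndarray, paired: bool = True
) -> tuple[float, float]:
    """Mean difference a-b and the two-sided t-test p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("contrast requires at least two observations per arm")
    if paired and a.size != b.size:
        raise ValidationError("paired contrast requires equal-length vectors")
    diff = float(a.mean() - b.mean())
    if paired:
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            p = 1.0 if np.allclose(d, 0.0) else 0.0
        else:
            p = float(sps.ttest_rel(a, b).pvalue)
    else:
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            p = 1.0 if np.isclose(diff, 0.0) else 0.0
        else:
            p = float(sps.ttest_ind(a, b).pvalue)
    return diff, p


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Step-down Holm adjustment, returned in the original order.

    Sorting the m raw p-values ascending, the i-th adjusted value is
    ``max_{j<=i} min(1, (m-j+1) * p_(j))``; the running maximum enforces
    monotonicity along the step-down path.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p must be a 1-D vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(adjusted_sorted)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


@dataclass
class ContrastTable:
    """Holm-adjusted contrast report for one experiment."""

    frame: pd.DataFrame

    def adjusted_p(self, contrast_name: str, metric: str) -> float:
        row = self.frame[
            (self.frame["contrast"] == contrast_name) & (self.frame["metric"] == metric)
        ]
        if row.empty:
            raise ConfigurationError(f"no contrast {contrast_name!r} / {metric!r}")
        return float(row["p_holm"].iloc[0])

    def difference(self, contrast_name: str, metric: str) -> float:
        row = self.frame[
            (self.frame["contrast"] == contrast_name) & (self.frame["metric"] == metric)
        ]
        if row.empty:
            raise ConfigurationError(f"no contrast {contrast_name!r} / {metric!r}")
        return float(row["difference"].iloc[0])

    def significant(self, contrast_name: str, metric: str, alpha: float = 0.05) -> bool:
        return self.adjusted_p(contrast_name, metric) < alpha


def contrast_table_from_metrics(
    per_iteration: pd.DataFrame,
    contrasts=STANDARD_CONTRASTS,
    paired: bool = True,
) -> ContrastTable:
    """Build the contrast report from a per-iteration metrics table.

    Expects columns named ``<arm>_accuracy`` / ``<arm>_auc`` as written by
    the evaluation harness.
    """
    rows = []
    for name, arm_a, arm_b in contrasts:
        for metric in ("accuracy", "auc"):
            ca, cb = f"{arm_a}_{metric}", f"{arm_b}_{metric}"
            if ca not in per_iteration.columns or cb not in per_iteration.columns:
                continue
            diff, p = contrast(
                per_iteration[ca].to_numpy(),
                per_iteration[cb].to_numpy(),
                paired=paired,
            )
            rows.append(
                {"contrast": name, "metric": metric, "difference": diff, "p_raw": p}
            )
    if not rows:
        raise ConfigurationError("no contrasts computable from the metrics table")
    frame = pd.DataFrame(rows)
    frame["p_holm"] = holm_adjust(frame["p_raw"].to_numpy())
    frame["stars"] = [star_code(p) for p in frame["p_holm"]]
    return ContrastTable(frame=frame)


def contrast_table(
    result: ExperimentResult,
    contrasts=STANDARD_CONTRASTS,
    paired: bool = True,
) -> ContrastTable:
    """All requested contrasts on both metrics, Holm-adjusted as one family.

    Contrasts whose arms were not run are silently dropped; the family is
    whatever remains (one table = one family).
    """
    rows = []
    for name, arm_a, arm_b in contrasts:
        if arm_a not in result.arms or arm_b not in result.arms:
            continue
        for metric in ("accuracy", "auc"):
            a = getattr(result.arms[arm_a], metric)
            b = getattr(result.arms[arm_b], metric)
            diff, p = contrast(a, b, paired=paired)
            rows.append(
                {"contrast": name, "metric": metric, "difference": diff, "p_raw": p}
            )
    if not rows:
        raise ConfigurationError("no contrasts computable from the result's arms")
    frame = pd.DataFrame(rows)
    frame["p_holm"] = holm_adjust(frame["p_raw"].to_numpy())
    frame["stars"] = [star_code(p) for p in frame["p_holm"]]
    return ContrastTable(frame=frame)
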