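# Methods

## Model and procedure

The package addresses sequential feature acquisition for binary diagnosis:
given a complete labeled pool of past cases and a partially observed
incoming patient, recommend the single most informative missing feature for
that patient.

The individualized recommender composes four steps. (1) Every pool case is
weighted by the reciprocal of its Euclidean distance to the patient over the
patient's observed features, $w_i = 1/(d_i + 10^{-9})$; weights are left
unnormalized, and the epsilon only prevents division by zero for exact
matches. (2) An L2-penalized logistic regression is fit on **all** pool
features with these case weights, minimizing
$\tfrac{1}{2C}\lVert\beta\rVert^2 + \sum_i w_i\,\ell_i(\beta)$ with the
intercept unpenalized. (3) The fitted linear model is attributed with the
exact linear Shapley explainer under feature independence,
$\phi_{ij} = \beta_j(x_{ij} - \bar x_j)$, against the unweighted pool mean;
attribution is on the log-odds scale, where rankings by mean absolute
attribution are scale-consistent (for a linear model the probability-scale
ranking coincides, since the sigmoid is monotone). (4) Features are ranked
by $I_j = \tfrac1N\sum_i|\phi_{ij}|$ and the top-ranked *missing* feature is
recommended; the ranking is computed over all columns first and filtered to
the missing set afterwards, so the reported ranking is always the full one.

Key assumptions: the pool is complete (no missing entries) and its encoding
is transferable to incoming patients; the observed "initial" features carry
information about *where* in feature space the patient sits, even when they
carry little outcome signal themselves; and a locally weighted linear model
is expressive enough once the neighborhood is homogeneous. The framework is
model-agnostic in principle; this implementation fixes the logistic
instantiation that the closed-form explainer makes cheap and exact.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `C` | 1.0 | inverse L2 strength of every logistic fit (unitless); the conventional default, frozen across all arms so contrasts reflect weighting, not tuning |
| distance epsilon | 1e-9 | additive floor in $1/(d+\varepsilon)$; makes an exact-match weight $10^9$ rather than infinite |
| solver | lbfgs, tol 1e-6, max 1000 iter | deterministic quasi-Newton; determinism is required for the reproducibility guarantees |
| scaling | min-max to [0,1] | Euclidean distances are range-sensitive; queries are encoded with the pool's parameters and clipped to [0,1] so out-of-range patients cannot produce pathological weights. `scaling=none` preserves raw values |
| `test_fraction` | 0.2 | evaluation split size (80/20) |
| `n_iterations` | 100 | repeated random splits per experiment; CI-sized runs in the test suite use 25 |
| accuracy threshold | 0.5 | default decision rule on the predicted probability |

## Evaluation harness

Initial features are chosen once per experiment as the *k least important*
features of an unweighted all-feature fit — emulating patients arriving with
routinely collected but weakly informative measurements. Each iteration
draws a fresh 80/20 split (single-class test splits are redrawn with a
deterministic reseed; a single-class training split is an error), computes
one global recommendation per iteration and one individualized
recommendation per test patient, reveals each patient's true value of the
recommended feature from the held-out row, fits the inference model on pool
columns initial ∪ {recommended} (plain, or patient-weighted for the LW
arms, with weights over exactly those columns — the patient has just
acquired the recommended value, so it participates in the distance), and
predicts that single patient. Accuracy is the fraction correct at threshold
0.5; AUC is the rank statistic of the pooled per-patient probabilities for
the iteration. Different patients in the same iteration may use different
column sets; identical column sets share a cached plain fit.

Arm contrasts use a paired t-test by default because arms share split seeds
(an unpaired variant is exposed); the family for Holm adjustment is one
report table — the four contrasts × two metrics of one dataset, or of one
initial-feature count in a sweep. Degenerate cases are conventionally
p = 1 for identical vectors and p = 0 for a constant non-zero paired
difference.

## Synthetic scenarios

The generator emulates case pools where the *location* of an added
feature's predictive power depends on an initial feature: `x` ~ U(0,1), a
balanced outcome independent of `x`, and added features that are
class-separable inside stated `x`-intervals (value $0.5 \pm$ U(margin, 0.5),
side set by the outcome and the association sign) and U(0,1) noise outside.
Defaults are n = 1000 and margin = 0.05. Scenario geometries: (1)
complementary halves; (2) association sign flipping within each feature's
half — the flip point is placed at 0.32 rather than mid-half so that a
pooled linear fit retains partial signal (best single-threshold accuracy
≈ 2·0.32 inside the half) while only a locally weighted fit can exploit the
feature fully; (3) overlapping regions [0, 0.7) and (0.3, 1]; (4) two
features identical in law over all of [0, 1]; (5) one dominant feature plus
two pure-noise columns. A separate timing table (500 × 100 i.i.d. noise
features, balanced label) supports the runtime benchmark.

What the generator does **not** emulate: class overlap inside predictive
regions (inside a region, separation is exact up to the margin), correlated
features, measurement error on the initial feature, or class imbalance.
Passing tests therefore demonstrate that the machinery identifies and
exploits region-structured informativeness when it exists; they do not
bound performance on noisy real-world pools, where within-region overlap
will lower all arms and shrink the individualized-vs-global gap.

## Numerical and design choices

- Shapley values are computed in closed form rather than sampled: for a
  linear model the interventional Shapley value is exactly
  $\beta_j(x_{ij}-\bar x_j)$, verified in the tests against coalition
  enumeration. The background mean is unweighted even for weighted fits, so
  global and individualized attributions share a reference point.
- Importance ties break by canonical (CSV header) column order everywhere,
  making recommendations deterministic.
- Distances at recommendation time use only the patient's observed
  features; at LW-inference time they include the just-acquired recommended
  feature — everything observed enters the notion of "similar patient".
- Weights are not normalized: the weighted likelihood is equivariant to a
  global weight scale only up to the fixed regularizer, and the reciprocal
  form is kept as specified.
- The delegated fit (scikit-learn, lbfgs) minimizes an objective that
  matches the stated weighted-penalized log-likelihood up to a positive
  factor; the tests confirm agreement with direct numerical minimization to
  1e-4 on small instances.
- The explanation-guided baseline is a simplified reimplementation from its
  mechanism description (nearest-neighbor pool, per-feature independent
  draws for imputation, a single unweighted logistic model as the explained
  predictor); it supports qualitative comparison only.

## Problem sizes

The bundled reproduction script runs scenarios 1–3 at n = 1000 with 100
iterations (the full protocol); the test suite runs the same protocol at 25
iterations, and unit tests use pools of 200–600 cases. These sizes give
split-to-split standard errors on arm means of well under 0.01 while
keeping a full run in minutes on one CPU.

## Known limitations

- The pool must be complete; there is no within-pool missing-data handling.
- Binary outcomes only; multi-class extension would change both the model
  and the attribution bookkeeping.
- Inverse-distance weights have heavy tails: in large pools the aggregate
  weight of distant cases can rival the local neighborhood, which is what
  makes the non-LW inference arms degrade in region-structured data — a
  feature for the evaluation, but a tunable kernel is deliberately out of
  scope here.
- One feature is recommended per pass; multi-step acquisition is available
  only by re-querying with the augmented record.
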