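# icare

Individualized clinical assessment recommendation: given a complete pool of
labeled past cases and an incoming patient for whom only some features have
been measured, decide **which missing feature (test, symptom, measurement)
to acquire next for this particular patient**.

Standard feature-selection methods (forward selection, lasso, a SHAP ranking
of a population model) give every patient the same recommendation. That is
wasteful whenever the informativeness of a test depends on what is already
known about the patient — e.g. when one follow-up test is decisive for
younger patients and a different one for older patients. This package
implements and evaluates a locally weighted alternative aimed at clinical
and biostatistical users working with tabular case data.

## Method

Let the pool of known cases be $(x_i, y_i)_{i=1}^{N}$ with $x_i \in \mathbb{R}^p$
and binary outcome $y_i$, and let an incoming patient observe feature subset
$S$ with values $q_S$. The individualized recommendation is built in four steps:

1. **Similarity weights.** Each case receives
   $w_i = 1/(d_i + 10^{-9})$, where
   $d_i = \lVert x_{iS} - q_S \rVert_2$ is the Euclidean distance over the
   patient's observed features only.
2. **Locally weighted model.** An L2-regularized logistic regression
   (C = 1, lbfgs) is fit on **all** pool features with per-case weights $w_i$,
   minimizing $\tfrac{1}{2C}\lVert\beta\rVert^2 + \sum_i w_i\,
   \ell(y_i, \beta_0 + \beta^\top x_i)$.
3. **Attribution.** Because the model is linear in log-odds, its Shapley
   values under feature independence are exact and closed-form:
   $\phi_{ij} = \beta_j (x_{ij} - \bar{x}_j)$, with the unweighted pool mean
   $\bar{x}$ as background. Feature importance is
   $I_j = \tfrac1N \sum_i |\phi_{ij}|$.
4. **Recommendation.** The highest-importance feature the patient is missing
   is recommended; ties break by column order.

Replacing $w_i$ with 1 gives the *global* recommendation (one answer for the
whole population). The same weighting can optionally be applied to the final
outcome-prediction model ("LW inference"). An evaluation harness compares
the four resulting arms (Global, Global+LW, individualized, individualized+LW)
over repeated 80/20 splits, with paired t-tests and step-down Holm correction
on the accuracy/AUC contrasts, against a ceiling model trained on all
features. Baseline selectors (sequential forward selection, lasso, and a
simplified imputation-based explanation-guided selector) plug into the same
harness.

## Worked example

Generate synthetic scenario 1 — an uninformative initial feature `x` plus
two added features that are each perfectly predictive on complementary
halves of the `x` range and pure noise elsewhere — then ask for a
recommendation for two patients:

```sh
$ icare simulate --scenario 1 --n 1000 --seed 7 --out s1.csv
$ printf 'x\n0.25\n' > patient.csv
$ icare recommend --cases s1.csv --patient patient.csv
feature,importance
feature_1,3.520540165924432
feature_2,0.6769492967613254
```

The patient at `x = 0.25` sits in the half where `feature_1` separates the
classes, and the locally weighted importance (mean |Shapley value| in
log-odds units) ranks it far above `feature_2`. A patient at `x = 0.75` gets
the mirror-image answer (`feature_2` at 4.05, `feature_1` at 0.61).

The evaluation harness quantifies the value of individualization on the same
data:

```sh
$ icare evaluate --cases s1.csv --k 1 --iterations 10 --arms global,icare --seed 3 --out res
$ cat res/k1_summary.csv
arm,mean_accuracy,sd_accuracy,mean_auc,sd_auc
global,0.7505,0.02692066533765879,0.7800454885317869,0.03104830132418881
icare,1.0,0.0,1.0,0.0
ceiling,0.7945000000000001,0.03113144176980349,0.8932268817330119,0.020037679096376868
$ icare compare --results res --out contrasts.csv
```

Individualized recommendation is essentially perfect (every patient is sent
to the feature that is informative *for them*) while the global arm, forced
to pick one feature for everyone, is right for only about half the patients;
`contrasts.csv` reports the +0.25 accuracy gap as Holm-significant (***).
Note the individualized arm can exceed the all-features "ceiling" here
because the pooled linear ceiling model cannot express the region-dependent
signal. `icare bench-timing` reports per-patient recommendation runtimes for
all five selectors on a noise benchmark table.

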