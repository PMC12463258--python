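from itertools import combinations
from math import factorial

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from icare.exceptions import DegenerateTrainingError, ValidationError
from icare.local_model import (
    LinearClassifier,
    background_mean,
    fit_weighted_logistic,
    linear_shap,
    mean_abs_importance,
    predict_prob,
)


def shapley_by_enumeration(model, x, mu):
    """Exact Shapley values of f(x)=b0+beta.x with mean-imputation of absent features.

    Enumerates all coalitions; the value of coalition S is the decision
    function with features outside S fixed at the background mean.
    """
    p = len(x)

    def value(subset):
        z = mu.copy()
        for j in subset:
            z[j] = x[j]
        return model.intercept + model.beta @ z

    phi = np.zeros(p)
    players = range(p)
    for j in players:
        others = [k for k in players if k != j]
        for size in range(p):
            for subset in combinations(others, size):
                weight = factorial(size) * factorial(p - size - 1) / factorial(p)
                phi[j] += weight * (value(subset + (j,)) - value(subset))
    return phi


def direct_objective_fit(X, y, w, C=1.0):
    """Numerically minimize (1/C) * 0.5*||beta||^2 + sum w_i * logloss_i."""
    n, p = X.shape

    def objective(params):
        beta, b0 = params[:p], params[p]
        z = b0 + X @ beta
        # stable log(1 + exp(-y'z)) with y' in {-1, +1}
        ys = 2 * y - 1
        loss = np.logaddexp(0.0, -ys * z)
        return 0.5 * beta @ beta / C + np.sum(w * loss)

    res = minimize(objective, np.zeros(p + 1), method="BFGS", tol=1e-12)
    return res.x[:p], res.x[p]


class TestWeightedFit:
    def test_matches_direct_objective_minimization(self, rng):
        X = rng.uniform(size=(18, 2))
        y = (X[:, 0] + 0.3 * rng.normal(size=18) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        w = rng.uniform(0.5, 3.0, size=18)
        model = fit_weighted_logistic(X, y, w=w)
        beta_ref, b0_ref = direct_objective_fit(X, y, w)
        assert np.allclose(model.beta, beta_ref, atol=1e-4)
        assert model.intercept == pytest.approx(b0_ref, abs=1e-4)

    def test_unit_weights_equal_unweighted(self, rng):
        X = rng.uniform(size=(40, 3))
        y = (X[:, 1] > 0.5).astype(int)
        m1 = fit_weighted_logistic(X, y, w=np.ones(40))
        m2 = fit_weighted_logistic(X, y, w=None)
        assert np.allclose(m1.beta, m2.beta, atol=1e-8)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-8)

    def test_doubling_weights_equals_halving_C(self, rng):
        """Scaling all weights by c rescales only the penalty, i.e. C -> c*C."""
        X = rng.uniform(size=(25, 2))
        y = (X[:, 0] > 0.4).astype(int)
        w = rng.uniform(0.5, 2.0, size=25)
        m1 = fit_weighted_logistic(X, y, w=2 * w, C=1.0)
        m2 = fit_weighted_logistic(X, y, w=w, C=2.0)
        assert np.allclose(m1.beta, m2.beta, atol=1e-5)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-5)

    def test_symmetric_data_gives_zero_intercept(self):
        x = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9]).reshape(-1, 1)
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_weighted_logistic(x, y)
        # symmetry puts the decision boundary at 0.5, up to solver tolerance
        assert model.intercept + model.beta[0] * 0.5 == pytest.approx(0.0, abs=1e-5)

    def test_single_class_raises_degenerate_error(self):
        with pytest.raises(DegenerateTrainingError):
            fit_weighted_logistic(np.zeros((4, 1)), np.zeros(4))

    def test_non_finite_rejected(self):
        X = np.array([[0.0], [np.inf]])
        with pytest.raises(ValidationError):
            fit_weighted_logistic(X, np.array([0, 1]))


class TestLinearShap:
    def test_hand_computed_attributions(self):
        model = LinearClassifier(beta=np.array([2.0, -1.0]), intercept=0.0)
        phi = linear_shap(model, np.array([[1.0, 0.0]]), np.array([0.5, 0.5]))
        assert np.allclose(phi, [[1.0, 0.5]])

    def test_background_row_attributes_to_zero(self):
        model = LinearClassifier(beta=np.array([3.0, 2.0]), intercept=-1.0)
        mu = np.array([0.4, 0.6])
        phi = linear_shap(model, mu.reshape(1, -1), mu)
        assert np.allclose(phi, 0.0)

    def test_matches_coalition_enumeration(self, rng):
        model = LinearClassifier(
            beta=rng.normal(size=3), intercept=float(rng.normal())
        )
        X = rng.uniform(size=(20, 3))
        mu = background_mean(X)
        phi = linear_shap(model, X, mu)
        for i in range(X.shape[0]):
            assert np.allclose(
                phi[i], shapley_by_enumeration(model, X[i], mu.copy()), atol=1e-9
            )

    def test_local_accuracy(self, rng):
        X = rng.uniform(size=(30, 4))
        y = (X[:, 0] > 0.5).astype(int)
        model = fit_weighted_logistic(X, y)
        mu = background_mean(X)
        phi = linear_shap(model, X, mu)
        f_x = model.decision_function(X)
        f_mu = model.decision_function(mu.reshape(1, -1))[0]
        assert np.allclose(phi.sum(axis=1), f_x - f_mu, atol=1e-9)

    def test_wrong_background_width_rejected(self):
        model = LinearClassifier(beta=np.array([1.0, 2.0]), intercept=0.0)
        with pytest.raises(ValidationError):
            linear_shap(model, np.zeros((2, 2)), np.zeros(3))


class TestImportanceRanking:
    def test_mean_absolute_arithmetic(self):
        phi = np.array([[1.0], [-1.0], [3.0]])
        ranking = mean_abs_importance(phi, ["a"])
        assert ranking.importance["a"] == pytest.approx(5 / 3)

    def test_zero_column_ranks_last(self):
        phi = np.array([[0.0, 1.0], [0.0, -2.0]])
        ranking = mean_abs_importance(phi, ["dead", "live"])
        assert ranking.order == ("live", "dead")
        assert ranking.importance["dead"] == 0.0

    def test_ties_broken_by_canonical_order(self):
        phi = np.array([[1.0, 1.0, 2.0]])
        ranking = mean_abs_importance(phi, ["b", "a", "c"])
        assert ranking.order == ("c", "b", "a")

    def test_closed_form_identity(self, rng):
        """mean|phi_j| must equal |beta_j| * mean|x_j - mu_j| exactly."""
        X = rng.uniform(size=(50, 3))
        y = (X[:, 2] > 0.5).astype(int)
        model = fit_weighted_logistic(X, y, feature_names=["a", "b", "c"])
        mu = background_mean(X)
        ranking = mean_abs_importance(linear_shap(model, X, mu), ["a", "b", "c"])
        expected = np.abs(model.beta) * np.abs(X - mu).mean(axis=0)
        got = np.array([ranking.importance[f] for f in ["a", "b", "c"]])
        assert np.allclose(got, expected, atol=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            mean_abs_importance(np.empty((0, 2)), ["a", "b"])


class TestPredictProb:
    def test_zero_decision_gives_half(self):
        model = LinearClassifier(beta=np.zeros(2), intercept=0.0)
        assert np.allclose(predict_prob(model, np.random.rand(5, 2)), 0.5)

    def test_probabilities_in_open_interval(self, rng):
        model = LinearClassifier(beta=np.array([4.0, -3.0]), intercept=1.0)
        p = predict_prob(model, rng.uniform(size=(100, 2)))
        assert ((p > 0) & (p < 1)).all()

    def test_monotone_in_positive_coefficient_feature(self, rng):
        model = LinearClassifier(beta=np.array([2.5, -1.0]), intercept=0.3)
        X = rng.uniform(size=(50, 2))
        bumped = X.copy()
        bumped[:, 0] += 0.1
        assert (predict_prob(model, bumped) >= predict_prob(model, X)).all()

    def test_agrees_with_sigmoid_of_decision(self, rng):
        model = LinearClassifier(beta=rng.normal(size=3), intercept=-0.7)
        X = rng.uniform(size=(20, 3))
        assert np.allclose(
            predict_prob(model, X), expit(model.decision_function(X))
        )
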