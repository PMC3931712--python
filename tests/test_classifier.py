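import math

import numpy as np
import pytest

from epimotif.classifier import (
    LRCModel,
    TrainingSet,
    cost,
    load_model,
    predict_proba,
    save_model,
    sigmoid,
    train,
)
from epimotif.evaluation import roc_curve


def logistic_data(rng, theta, m):
    d = len(theta) - 1
    X = rng.normal(size=(m, d))
    p = sigmoid(theta[0] + X @ np.asarray(theta[1:]))
    y = (rng.uniform(size=m) < p).astype(int)
    return X, y


class TestSigmoid:
    def test_fixed_points_and_asymptotes(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(1000.0) == 1.0  # saturates without overflow
        assert sigmoid(-1000.0) == 0.0

    def test_symmetry_identity(self):
        z = np.linspace(-30, 30, 101)
        assert np.allclose(sigmoid(z) + sigmoid(-z), 1.0)


class TestCost:
    def test_zero_theta_gives_ln2(self):
        rng = np.random.default_rng(0)
        X = np.hstack([np.ones((40, 1)), rng.normal(size=(40, 3))])
        y = rng.integers(0, 2, size=40).astype(float)
        J, _ = cost(np.zeros(4), X, y)
        assert J == pytest.approx(math.log(2), abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        eps = 1e-5
        for _ in range(50):
            m, d = int(rng.integers(5, 40)), int(rng.integers(1, 6))
            X = np.hstack([np.ones((m, 1)), rng.normal(size=(m, d))])
            y = rng.integers(0, 2, size=m).astype(float)
            theta = rng.normal(scale=0.8, size=d + 1)
            _, grad = cost(theta, X, y)
            for k in range(d + 1):
                e = np.zeros(d + 1)
                e[k] = eps
                jp, _ = cost(theta + e, X, y)
                jm, _ = cost(theta - e, X, y)
                fd = (jp - jm) / (2 * eps)
                assert abs(grad[k] - fd) <= 1e-6 * max(1.0, abs(fd))

    def test_perfect_separation_cost_vanishes_along_separator(self):
        X = np.array([[1.0, -2.0], [1.0, -1.0], [1.0, 1.0], [1.0, 2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        costs = [cost(np.array([0.0, s]), X, y)[0] for s in (1, 10, 100)]
        assert costs[0] > costs[1] > costs[2]
        assert costs[2] < 1e-10

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cost(np.zeros(1), np.empty((0, 1)), np.empty(0))


class TestTrain:
    def test_separated_distances_learn_negative_weight(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(100, 30, size=200)
        neg = rng.normal(2000, 300, size=200)
        X = np.r_[pos, neg][:, None]
        y = np.r_[np.ones(200), np.zeros(200)].astype(int)
        model = train(TrainingSet(X=X, y=y, feature_names=["dist"]))
        assert model.theta[1] < 0  # larger distance -> lower probability
        auc = roc_curve(predict_proba(model, X), y).auc
        assert auc >= 0.99

    def test_permuted_labels_give_chance_level_auc(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(2000, 1))
        y = np.r_[np.ones(1000), np.zeros(1000)].astype(int)
        rng.shuffle(y)
        model = train(TrainingSet(X=X[:1000], y=y[:1000], feature_names=["f"]))
        auc = roc_curve(predict_proba(model, X[1000:]), y[1000:]).auc
        assert 0.45 <= auc <= 0.55

    def test_training_on_standardized_data_is_idempotent(self):
        rng = np.random.default_rng(4)
        X, y = logistic_data(rng, [0.2, 1.0, -1.5], 500)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        m1 = train(TrainingSet(X=Z, y=y, feature_names=["a", "b"]))
        Z2 = (Z - Z.mean(axis=0)) / Z.std(axis=0)
        m2 = train(TrainingSet(X=Z2, y=y, feature_names=["a", "b"]))
        assert np.allclose(m1.theta, m2.theta, atol=1e-6)

    def test_single_class_and_nonfinite_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError):
            train(TrainingSet(X=X, y=np.ones(5, dtype=int), feature_names=["f"]))
        bad = np.array([[1.0], [np.nan], [2.0], [3.0]])
        with pytest.raises(ValueError):
            train(TrainingSet(
                X=bad, y=np.array([0, 1, 0, 1]), feature_names=["f"]
            ))

    def test_optimum_independent_of_initialization(self):
        # J is convex: a random restart reaches the same final cost
        rng = np.random.default_rng(5)
        X, y = logistic_data(rng, [0.3, 1.2, -0.7], 400)
        ts = TrainingSet(X=X, y=y, feature_names=["a", "b"])
        m0 = train(ts)
        m1 = train(ts, theta0=rng.normal(scale=2.0, size=3))
        assert abs(
            m0.training_meta["final_cost"] - m1.training_meta["final_cost"]
        ) <= 1e-6

    def test_parameter_recovery_on_simulated_logistic_model(self):
        rng = np.random.default_rng(6)
        theta_true = np.array([0.5, 1.5, -2.0, 0.8])
        X, y = logistic_data(rng, theta_true, 5000)
        model = train(TrainingSet(X=X, y=y, feature_names=list("abc")))
        # features are ~N(0,1) so standardization barely changes scale;
        # compare on the original scale
        w = model.theta[1:] / model.std
        b = model.theta[0] - float(np.sum(model.theta[1:] * model.mean / model.std))
        est = np.r_[b, w]
        assert np.all(np.abs(est - theta_true) <= 0.15 * np.abs(theta_true))


class TestPredict:
    @pytest.fixture()
    def model(self):
        rng = np.random.default_rng(7)
        X, y = logistic_data(rng, [0.0, -1.0], 600)
        return train(TrainingSet(X=X, y=y, feature_names=["dist"]))

    def test_training_mean_maps_to_intercept_probability(self, model):
        p = predict_proba(model, model.mean.copy())
        assert p == pytest.approx(float(sigmoid(model.theta[0])), abs=1e-12)

    def test_monotone_in_negative_weight_feature(self, model):
        assert model.theta[1] < 0
        xs = np.linspace(-3, 3, 20)[:, None]
        p = predict_proba(model, xs)
        assert np.all(np.diff(p) < 0)

    def test_dimension_mismatch_raises(self, model):
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros(3))

    def test_round_trip_is_bit_identical(self, model, tmp_path):
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        x = np.array([[0.3], [-1.2], [2.4]])
        assert np.array_equal(predict_proba(model, x), predict_proba(loaded, x))


def test_constant_features_are_dropped_with_warning():
    rng = np.random.default_rng(8)
    X = np.hstack([rng.normal(size=(100, 1)), np.full((100, 1), 7.0)])
    y = (X[:, 0] > 0).astype(int)
    with pytest.warns(UserWarning, match="constant"):
        model = train(TrainingSet(X=X, y=y, feature_names=["real", "flat"]))
    assert model.feature_names == ["real"]
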