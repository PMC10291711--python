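"""Forward pass, likelihood, training and the ensemble protocol."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.special import expit

from flychrome.ann_engine import (
    MLPModel,
    TaskSpec,
    TrainConfig,
    _objective,
    _shapes,
    accuracy,
    classify,
    forward,
    nll,
    run_ensemble,
    train_best_of,
    train_single,
)


def _toy_model(k=2, n_hidden=2):
    W1 = np.array([[0.5, -1.0], [0.25, 0.75]])[:k, :n_hidden]
    b1 = np.array([0.1, -0.2])[:n_hidden]
    W2 = np.array([1.5, -0.5])[:n_hidden]
    return MLPModel(("R8p", "R8y")[:k], W1, b1, W2, 0.3)


def _separable_toy(rng, n=40):
    x0 = rng.normal([-2, -2], 0.5, (n // 2, 2))
    x1 = rng.normal([2, 2], 0.5, (n // 2, 2))
    X = np.vstack([x0, x1])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    return X, y


class TestForward:
    def test_zero_weights_give_half(self):
        m = MLPModel(("R8p",), np.zeros((1, 3)), np.zeros(3), np.zeros(3), 0.0)
        assert forward(m, [[0.7]])[0] == pytest.approx(0.5)

    def test_large_output_bias_saturates_to_one(self):
        m = MLPModel(("R8p",), np.zeros((1, 3)), np.zeros(3), np.zeros(3), 50.0)
        assert forward(m, [[0.0]])[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_sigmoid_chain(self):
        m = _toy_model()
        x = np.array([0.4, -0.6])
        h = expit(x @ m.W1 + m.b1)
        expected = expit(h @ m.W2 + m.b2)
        assert forward(m, x)[0] == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="features"):
            forward(_toy_model(), [[1.0, 2.0, 3.0]])


class TestClassify:
    def test_threshold_at_half_with_tie_as_positive(self):
        m = MLPModel(("R8p",), np.zeros((1, 3)), np.zeros(3), np.zeros(3), 0.0)
        assert classify(m, [[0.0]])[0] == 1  # p = 0.5 exactly
        m_neg = MLPModel(("R8p",), np.zeros((1, 3)), np.zeros(3), np.zeros(3), -0.1)
        assert classify(m_neg, [[0.0]])[0] == 0

    def test_agrees_with_logit_sign(self, rng):
        m = _toy_model()
        X = rng.normal(size=(50, 2))
        p = forward(m, X)
        assert np.array_equal(classify(m, X), (p >= 0.5).astype(int))


class TestNll:
    def test_uninformative_model_gives_n_log_two(self):
        m = MLPModel(("R8p",), np.zeros((1, 3)), np.zeros(3), np.zeros(3), 0.0)
        X = np.zeros((10, 1))
        y = np.r_[np.ones(5), np.zeros(5)]
        assert nll(m, X, y) == pytest.approx(10 * np.log(2))

    def test_confident_correct_predictions_near_zero(self):
        m = MLPModel(("R8p",), np.full((1, 1), 50.0), np.zeros(1),
                     np.full(1, 50.0), -25.0)
        X = np.array([[1.0], [-1.0]])
        assert nll(m, X, np.array([1.0, 0.0])) < 1e-6

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            nll(_toy_model(), np.empty((0, 2)), np.empty(0))

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) > 0.5).astype(float)
        theta = rng.normal(size=_shapes(3, 3)) * 0.5
        _, grad = _objective(theta, X, y, 3, 1e-3, "logistic")
        numeric = approx_fprime(
            theta, lambda t: _objective(t, X, y, 3, 1e-3, "logistic")[0], 1e-7)
        assert np.allclose(grad, numeric, rtol=1e-5, atol=1e-5)


class TestTraining:
    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        X, y = _separable_toy(rng)
        model = train_single(X, y, ("R8p", "R8y"), TrainConfig(), 0)
        assert accuracy(model, X, y) == 1.0

    def test_same_data_and_seed_reproduce_weights(self, rng):
        X, y = _separable_toy(rng)
        m1 = train_single(X, y, ("R8p", "R8y"), TrainConfig(), 3)
        m2 = train_single(X, y, ("R8p", "R8y"), TrainConfig(), 3)
        assert np.array_equal(m1.W1, m2.W1) and m1.b2 == m2.b2

    def test_single_class_data_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="both classes"):
            train_single(X, np.ones(10), ("R8p", "R8y"), TrainConfig(), 0)

    def test_best_of_selects_minimum_penalized_score(self, rng):
        X, y = _separable_toy(rng)
        cfg = TrainConfig(n_inits=5)
        seq = np.random.SeedSequence(7)
        best = train_best_of(X, y, ("R8p", "R8y"), cfg, seq)
        candidates = [train_single(X, y, ("R8p", "R8y"), cfg, s)
                      for s in np.random.SeedSequence(7).spawn(5)]

        def score(m):
            return m.training_nll + cfg.weight_decay * (np.sum(m.W1**2) + np.sum(m.W2**2))

        assert score(best) == pytest.approx(min(score(c) for c in candidates))

    def test_best_of_one_equals_single_training(self, rng):
        X, y = _separable_toy(rng)
        cfg = TrainConfig(n_inits=1)
        best = train_best_of(X, y, ("R8p", "R8y"), cfg, 11)
        single = train_single(X, y, ("R8p", "R8y"), cfg,
                              np.random.SeedSequence(11).spawn(1)[0])
        assert np.array_equal(best.W1, single.W1)


class TestEnsembleProtocol:
    def test_ensemble_reproducible_bit_for_bit(self, dataset):
        cfg = TrainConfig(n_inits=3, n_reps=3, master_seed=99)
        spec = TaskSpec("animal", ("R8p", "R8y"))
        r1 = run_ensemble(dataset, spec, cfg)
        r2 = run_ensemble(dataset, spec, cfg)
        assert np.array_equal(r1.accuracies, r2.accuracies)
        for m1, m2 in zip(r1.models, r2.models):
            assert np.array_equal(m1.W1, m2.W1)

    def test_splits_are_60_40_with_both_classes(self, dataset):
        cfg = TrainConfig(n_inits=2, n_reps=4, master_seed=5)
        result = run_ensemble(dataset, TaskSpec("shaded"), cfg)
        y = TaskSpec("shaded").labels(dataset.frame)
        for train, test in result.splits:
            assert len(train) == round(0.6 * 288) and len(test) == 288 - len(train)
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.unique(y[train])) == 2

    def test_permuted_labels_give_chance_accuracy(self, dataset, rng):
        frame = dataset.frame.copy()
        frame["class_label"] = rng.permutation(frame["class_label"].to_numpy())
        cfg = TrainConfig(n_inits=5, n_reps=5, master_seed=17)
        result = run_ensemble(frame, TaskSpec("animal"), cfg)
        assert 0.4 <= result.mean_accuracy <= 0.6

    def test_hidden_layer_never_far_below_logistic_regression(self, dataset):
        """The k->3->1 net's held-out accuracy should not trail its linear special case."""
        from sklearn.linear_model import LogisticRegression
        cfg = TrainConfig(n_inits=5, n_reps=5, master_seed=23)
        spec = TaskSpec("animal")
        result = run_ensemble(dataset, spec, cfg)
        X = spec.design(dataset.frame)
        y = spec.labels(dataset.frame)
        lr_accs = []
        for train, test in result.splits:
            lr = LogisticRegression(max_iter=2000).fit(X[train], y[train])
            lr_accs.append(lr.score(X[test], y[test]))
        assert result.mean_accuracy >= np.mean(lr_accs) - 0.05

    def test_serialization_round_trip(self, dataset, tmp_path):
        from flychrome.ann_engine import EnsembleResult
        cfg = TrainConfig(n_inits=2, n_reps=2, master_seed=31)
        result = run_ensemble(dataset, TaskSpec("shaded"), cfg)
        path = tmp_path / "ens.json"
        result.to_json(path)
        back = EnsembleResult.from_json(path)
        assert np.array_equal(back.accuracies, result.accuracies)
        X = TaskSpec("shaded").design(dataset.frame)
        assert np.allclose(forward(back.models[0], X), forward(result.models[0], X))


class TestTaskSpec:
    def test_animal_labels_ignore_condition(self, dataset):
        y = TaskSpec("animal").labels(dataset.frame)
        assert y.sum() == 144

    def test_shaded_labels_ignore_class(self, dataset):
        y = TaskSpec("shaded").labels(dataset.frame)
        assert y.sum() == 144

    def test_invalid_task_and_subset_rejected(self):
        with pytest.raises(ValueError):
            TaskSpec("prey")
        with pytest.raises(ValueError):
            TaskSpec("animal", ())
        with pytest.raises(ValueError):
            TaskSpec("animal", ("R9z",))
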