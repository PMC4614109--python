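"""Scoring, initialization, robust fitness, GA refinement, prediction."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from elmqsar import (
    LabeledDataset,
    OptimizerConfig,
    SyntheticConfig,
    andrews_fitness,
    classify_scores,
    compute_threshold,
    evaluate_predictions,
    fit_initial_weights,
    generate,
    optimize_weights_ga,
    rss,
    standardize,
    train,
    train_initial,
    weighted_sum,
)
from elmqsar.errors import ConfigError, DegenerateProblemError


class TestWeightedSumAndRss:
    def test_arithmetic(self):
        assert weighted_sum(np.array([1.0, -2.0]), np.array([3.0, 1.0])) == 1.0
        assert weighted_sum(np.array([5.0, 7.0]), np.zeros(2)) == 0.0

    def test_matches_independent_dot(self, rng):
        w = rng.standard_normal(10)
        x = rng.standard_normal(10)
        expected = sum(wi * xi for wi, xi in zip(w, x))
        assert math.isclose(weighted_sum(w, x), expected, rel_tol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            weighted_sum(np.ones(3), np.ones(2))

    def test_rss_perfect_and_zero(self, rng):
        X = rng.standard_normal((8, 2))
        w = np.array([0.5, -1.0])
        y = X @ w
        assert rss(w, X, y) == 0.0
        y2 = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        assert rss(np.zeros(2), X, y2) == pytest.approx(float(y2 @ y2))

    def test_rss_matches_loop(self, rng):
        X = rng.standard_normal((15, 3))
        w = rng.standard_normal(3)
        y = rng.standard_normal(15)
        expected = sum((yi - float(w @ xi)) ** 2 for xi, yi in zip(X, y))
        assert math.isclose(rss(w, X, y), expected, abs_tol=1e-12)


class TestInitialWeights:
    def test_identity_and_proportional_slopes(self):
        assert fit_initial_weights(
            np.array([[0.0], [1.0], [2.0]]), np.array([0.0, 1.0, 2.0])
        )[0] == pytest.approx(1.0)
        assert fit_initial_weights(
            np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 4.0, 6.0])
        )[0] == pytest.approx(2.0)

    def test_worked_example_slopes(self, worked_example):
        dataset, expected = worked_example
        w = fit_initial_weights(dataset.matrix.values, dataset.y)
        for j, name in enumerate(dataset.matrix.descriptor_names):
            assert w[j] == pytest.approx(expected[name], abs=1e-12)

    def test_matches_1d_numeric_minimizer(self, rng):
        # each slope must minimize the per-descriptor RSS (with intercept)
        X = rng.standard_normal((40, 5))
        y = rng.standard_normal(40)
        w = fit_initial_weights(X, y)
        for j in range(5):
            x = X[:, j]

            def per_desc_rss(wj, x=x):
                resid = (y - y.mean()) - wj * (x - x.mean())
                return float(resid @ resid)

            best = minimize_scalar(
                per_desc_rss, method="brent", options={"xtol": 1e-12}
            ).x
            assert w[j] == pytest.approx(best, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateProblemError):
            fit_initial_weights(np.ones((5, 1)), np.arange(5.0))


class TestAndrewsFitness:
    def test_zero_residuals_attain_maximum(self):
        assert andrews_fitness(np.zeros(5), a=1.339) == 0.0

    def test_boundary_continuity(self):
        a = 1.339
        inside = -andrews_fitness(np.array([math.pi * a]), a)
        outside = -andrews_fitness(np.array([math.pi * a + 1e-9]), a)
        assert inside == pytest.approx(2 * a * a, rel=1e-12)
        assert outside == pytest.approx(2 * a * a, rel=1e-12)

    def test_small_residual_taylor_limit(self):
        a = 1.339
        r = 0.01 * a
        rho = -andrews_fitness(np.array([r]), a)
        assert rho / (r * r / 2) == pytest.approx(1.0, abs=1e-3)

    def test_large_a_limit_is_half_rss(self, rng):
        residuals = rng.standard_normal(50)
        a = 1e6
        target = float(residuals @ residuals) / 2.0
        assert -andrews_fitness(residuals, a) == pytest.approx(target, rel=1e-6)

    def test_invalid_constant(self):
        with pytest.raises(ConfigError):
            andrews_fitness(np.zeros(3), a=0.0)


class TestThresholdAndPredict:
    def test_stated_modes(self):
        scores = np.array([-1.0, -1.0, 1.0, 1.0])
        labels = np.array([1, 1, 2, 2])
        assert compute_threshold(scores, labels, "midpoint") == 0.0
        assert compute_threshold(scores, labels, "literal_difference") == -2.0

    def test_degenerate_equal_scores(self):
        scores = np.full(4, 3.7)
        labels = np.array([1, 2, 1, 2])
        assert compute_threshold(scores, labels, "midpoint") == pytest.approx(3.7)

    def test_matches_hand_computation(self, rng):
        scores = rng.standard_normal(30)
        labels = rng.choice([1, 2], size=30)
        act = scores[labels == 1].mean()
        inact = scores[labels == 2].mean()
        assert compute_threshold(scores, labels, "midpoint") == pytest.approx(
            (act + inact) / 2, abs=1e-12
        )
        assert compute_threshold(
            scores, labels, "literal_difference"
        ) == pytest.approx(act - inact, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateProblemError):
            compute_threshold(np.ones(3), np.array([1, 1, 1]))

    def test_decision_rule_and_tie(self):
        th = 0.5
        assert classify_scores(np.array([th - 0.1]), th)[0] == 1
        assert classify_scores(np.array([th]), th)[0] == 2
        assert classify_scores(np.array([th + 0.1]), th)[0] == 2


class TestOptimizeWeights:
    def test_zero_generations_is_identity(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.choice([1.0, 2.0], size=20)
        w0 = fit_initial_weights(X, y)
        w, trace = optimize_weights_ga(
            X, y, w0, OptimizerConfig(max_generations=0, seed=1)
        )
        np.testing.assert_array_equal(w, w0)
        assert len(trace) == 1

    def test_elitism_never_degrades_fitness(self, rng):
        from elmqsar.elm_core import _fitness_batch

        X = rng.standard_normal((50, 4))
        w_true = np.array([1.0, -0.5, 0.25, 2.0])
        y = X @ w_true
        cfg = OptimizerConfig(max_generations=50, seed=3)
        w, trace = optimize_weights_ga(X, y, w_true, cfg)
        assert rss(w, X, y) <= rss(w_true, X, y) + 1e-9
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))
        init_fit = float(_fitness_batch(w_true[None, :], X, y, cfg)[0])
        assert trace[-1] >= init_fit - 1e-12

    def test_sum_of_squares_fitness_reduces_rss(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.choice([1.0, 2.0], size=60)
        w0 = np.zeros(3)
        cfg = OptimizerConfig(
            max_generations=200, fitness_kind="sum_of_squares", seed=9
        )
        w, _ = optimize_weights_ga(X, y, w0, cfg)
        assert rss(w, X, y) <= rss(w0, X, y)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((30, 3))
        y = rng.choice([1.0, 2.0], size=30)
        w0 = fit_initial_weights(X, y)
        cfg = OptimizerConfig(max_generations=60, seed=11)
        w1, t1 = optimize_weights_ga(X, y, w0, cfg)
        w2, t2 = optimize_weights_ga(X, y, w0, cfg)
        np.testing.assert_array_equal(w1, w2)
        assert t1 == t2


class TestTrain:
    def test_zero_generation_model_equals_initial_baseline(self, small_synth):
        dataset, truth = small_synth
        names = truth.informative_names
        a = train(dataset, names, OptimizerConfig(max_generations=0, seed=1))
        b = train_initial(dataset, names)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.threshold == b.threshold

    def test_same_seed_identical_models(self, tmp_path, small_synth):
        from elmqsar import load_model, save_model

        dataset, truth = small_synth
        cfg = OptimizerConfig(max_generations=40, seed=5)
        m1 = train(dataset, truth.informative_names, cfg)
        m2 = train(dataset, truth.informative_names, cfg)
        p1, p2 = tmp_path / "a.elm", tmp_path / "b.elm"
        save_model(m1, str(p1))
        save_model(m2, str(p2))
        assert p1.read_text() == p2.read_text()

    def test_optimized_beats_chance(self, small_synth):
        dataset, truth = small_synth
        model = train(
            dataset, truth.informative_names,
            OptimizerConfig(max_generations=150, seed=2),
        )
        report = evaluate_predictions(model.predict(dataset.matrix), dataset.labels)
        assert report.mcc > 0.0

    def test_separable_training_set_fully_recovered(self):
        dataset, truth = generate(SyntheticConfig(seed=4, effect_size=6.0))
        model = train_initial(dataset, truth.informative_names)
        report = evaluate_predictions(model.predict(dataset.matrix), dataset.labels)
        assert report.acc == 100.0

    def test_prediction_invariant_to_raw_units(self, small_synth):
        dataset, truth = small_synth
        model = train_initial(dataset, truth.informative_names)
        pred = model.predict(dataset.matrix)
        # rescale the raw data and retrain: standardization absorbs units
        rescaled = dataset.matrix
        rescaled = type(rescaled)(
            rescaled.compound_ids,
            rescaled.descriptor_names,
            rescaled.values * 3.5 + 11.0,
        )
        ds2 = LabeledDataset(rescaled, dataset.labels.copy())
        model2 = train_initial(ds2, truth.informative_names)
        np.testing.assert_array_equal(model2.predict(rescaled), pred)

    def test_empty_subset_rejected(self, small_synth):
        dataset, _ = small_synth
        with pytest.raises(DegenerateProblemError):
            train(dataset, [], OptimizerConfig())
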