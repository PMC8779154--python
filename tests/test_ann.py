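"""ANN correctness: forward oracle, gradient check, training, round trips."""

from dataclasses import replace

import numpy as np
import pytest

import emgsleeve as es
from emgsleeve import GestureClass, TrainConfig
from emgsleeve.ann import (AnnModel, batch_loss, evaluate, forward,
                           gradient_check, init_model, load_model, save_model,
                           threshold_output, train)
from emgsleeve.features import FeatureVector


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestInit:
    def test_same_seed_identical_parameters(self):
        a, b = init_model(seed=3), init_model(seed=3)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.w2, b.w2)

    def test_different_seeds_differ(self):
        assert not np.array_equal(init_model(seed=3).w1, init_model(seed=4).w1)

    def test_weights_within_glorot_bounds_biases_zero(self):
        m = init_model(seed=0)
        r1 = np.sqrt(6.0 / (21 + 3))
        r2 = np.sqrt(6.0 / (3 + 3))
        assert np.all(np.abs(m.w1) <= r1) and np.all(np.abs(m.w2) <= r2)
        assert np.all(m.b1 == 0) and np.all(m.b2 == 0)

    def test_default_architecture_is_21_3_3(self):
        assert init_model(seed=0).layer_sizes == (21, 3, 3)


class TestForward:
    def test_zero_network_outputs_half(self):
        m = AnnModel(np.zeros((3, 21)), np.zeros(3), np.zeros((3, 3)),
                     np.zeros(3))
        np.testing.assert_allclose(forward(m, np.ones(21)), 0.5)

    def test_outputs_bounded_for_extreme_inputs(self):
        m = init_model(seed=1)
        for scale in (1e6, -1e6):
            out = forward(m, np.full(21, scale))
            assert np.all(out > 0) and np.all(out < 1)

    def test_toy_network_matches_pencil_arithmetic(self):
        # 2-2-1 network evaluated by hand: sigmoid(W2 sigmoid(W1 x + b1) + b2)
        m = AnnModel(np.array([[1.0, -1.0], [0.5, 0.5]]), np.array([0.0, -1.0]),
                     np.array([[1.0, 2.0]]), np.array([0.5]))
        x = np.array([1.0, 2.0])
        h = sigmoid(np.array([1 - 2, 0.5 + 1 - 1]))
        expected = sigmoid(h[0] + 2 * h[1] + 0.5)
        assert forward(m, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="features"):
            forward(init_model(seed=0), np.ones(20))


class TestThreshold:
    def test_componentwise_strict_threshold(self):
        assert threshold_output(np.array([0.7, 0.2, 0.9])) == (1, 0, 1)

    def test_exact_half_ties_fail_safe_to_rest(self):
        code = threshold_output(np.array([0.5, 0.5, 0.5]))
        assert code == (0, 0, 0)
        assert GestureClass.from_code(code) is GestureClass.Rest

    def test_saturated_outputs_decode_to_all_fingers(self):
        code = threshold_output(np.array([1.0, 1.0, 1.0]))
        assert GestureClass.from_code(code) is GestureClass.AllFingers


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        worst = 0.0
        for seed in range(3):
            m = init_model(seed=seed)
            x = rng.normal(size=21)
            t = rng.integers(0, 2, size=3).astype(float)
            worst = max(worst, gradient_check(m, x, t))
        assert worst < 1e-6

    def test_zero_gradient_when_output_equals_target(self):
        m = AnnModel(np.zeros((3, 21)), np.zeros(3), np.zeros((3, 3)),
                     np.zeros(3))
        err = gradient_check(m, np.zeros(21), np.full(3, 0.5))
        assert err < 1e-6  # both gradients ~ 0

    def test_checker_detects_perturbed_gradient(self, rng):
        # negative control: a 1% multiplicative error must be flagged
        from emgsleeve import ann as ann_mod
        m = init_model(seed=5)
        x, t = rng.normal(size=21), np.array([1.0, 0.0, 1.0])
        orig = ann_mod._gradients
        try:
            ann_mod._gradients = lambda *a: tuple(g * 1.01 for g in orig(*a))
            assert gradient_check(m, x, t) > 1e-4
        finally:
            ann_mod._gradients = orig


class TestTraining:
    def _toy_features(self, rng, n=60):
        """Linearly separable 21-d features for three single-group poses."""
        feats = []
        classes = [GestureClass.Index, GestureClass.Middle, GestureClass.RingPinky]
        for i in range(n):
            g = classes[i % 3]
            v = rng.normal(scale=0.02, size=21)
            v[3 * (i % 3) * 2] += 1.0  # one hot-ish dimension per class
            feats.append(FeatureVector(i, 0.27 * i, v, g))
        return feats

    def test_zero_learning_rate_is_a_no_op(self, rng):
        m = init_model(seed=2)
        feats = self._toy_features(rng)
        cfg = TrainConfig(learning_rate=0.0, epochs=3, seed=0)
        m2, _ = train(m, feats, cfg)
        np.testing.assert_array_equal(m.w1, m2.w1)
        np.testing.assert_array_equal(m.w2, m2.w2)

    def test_single_sample_memorized(self, rng):
        m = init_model(seed=0)
        feats = [FeatureVector(0, 0.0, rng.normal(size=21),
                               GestureClass.IndexMiddle)]
        cfg = TrainConfig(learning_rate=0.5, epochs=6000, seed=0)
        m2, history = train(m, feats, cfg)
        assert history[-1] < 0.01
        assert es.predict(m2, feats[0].values) is GestureClass.IndexMiddle

    def test_identical_seeds_identical_histories(self, rng):
        feats = self._toy_features(rng)
        cfg = TrainConfig(learning_rate=0.05, epochs=50, seed=9)
        _, h1 = train(init_model(seed=1), feats, cfg)
        _, h2 = train(init_model(seed=1), feats, cfg)
        np.testing.assert_array_equal(h1, h2)

    def test_loss_descends_over_500_epoch_spans(self, rng):
        feats = self._toy_features(rng)
        cfg = TrainConfig(learning_rate=0.01, epochs=2000, seed=4)
        _, h = train(init_model(seed=4), feats, cfg)
        spans = h[:-500] - h[500:]          # positive where loss decreased
        assert np.mean(spans < 0) <= 0.05   # <=5% transient violations
        assert h[-1] < h[0]

    def test_unlabeled_features_rejected(self, rng):
        feats = [FeatureVector(0, 0.0, rng.normal(size=21), None)]
        with pytest.raises(ValueError, match="labeled"):
            train(init_model(seed=0), feats, TrainConfig(epochs=1))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train(init_model(seed=0), [], TrainConfig(epochs=1))


class TestEvaluate:
    def test_constant_rest_model_on_rest_set(self, rng):
        # strongly negative output biases force (0,0,0) = Rest always
        m = init_model(seed=0)
        m.b2 = np.full(3, -20.0)
        feats = [FeatureVector(i, 0.0, rng.normal(size=21), GestureClass.Rest)
                 for i in range(10)]
        cm = evaluate(m, feats)
        assert cm.class_accuracy(GestureClass.Rest) == 1.0

    def test_counts_conserve_test_set_size(self, rng):
        m = init_model(seed=0)
        feats = [FeatureVector(i, 0.0, rng.normal(size=21),
                               list(GestureClass)[i % 8]) for i in range(40)]
        cm = evaluate(m, feats)
        assert cm.total == 40

    def test_percentage_rows_sum_to_100(self, rng):
        m = init_model(seed=0)
        feats = [FeatureVector(i, 0.0, rng.normal(size=21),
                               list(GestureClass)[i % 8]) for i in range(64)]
        cm = evaluate(m, feats)
        sums = cm.percentages.sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, rtol=1e-9)


class TestSerialization:
    def _fitted_model(self):
        m = init_model(seed=6)
        m.norm_constants = np.linspace(0.5, 2.0, 21)
        m.wamp_epsilon = 1.25
        return m

    def test_roundtrip_bitwise_equal_predictions(self, tmp_path, rng):
        m = self._fitted_model()
        save_model(m, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        X = rng.normal(size=(100, 21))
        for x in X:
            np.testing.assert_array_equal(forward(m, x), forward(back, x))
        assert back.wamp_epsilon == m.wamp_epsilon

    def test_missing_normalization_block_fails(self, tmp_path):
        m = self._fitted_model()
        save_model(m, tmp_path / "m.json")
        import json
        doc = json.loads((tmp_path / "m.json").read_text())
        del doc["norm_constants"]
        (tmp_path / "m2.json").write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="norm_constants"):
            load_model(tmp_path / "m2.json")

    def test_shape_mismatch_fails(self, tmp_path):
        m = self._fitted_model()
        save_model(m, tmp_path / "m.json")
        import json
        doc = json.loads((tmp_path / "m.json").read_text())
        doc["layer_sizes"] = [21, 4, 3]  # hand-edited, matrices still 3-wide
        (tmp_path / "m2.json").write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="layer_sizes|shape"):
            load_model(tmp_path / "m2.json")

    def test_unfitted_model_refuses_to_save(self, tmp_path):
        with pytest.raises(ValueError, match="normalization"):
            save_model(init_model(seed=0), tmp_path / "m.json")
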