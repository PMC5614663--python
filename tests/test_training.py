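"""Loss, optimizer and evaluation behaviour, including a finite-difference
check of the backpropagation engine."""

import math

import numpy as np
import pytest

from gpdnet import (LabeledImageSet, TrainConfig, WeightStore, build_gpdnet,
                    cross_entropy_loss, evaluate_accuracy, initialize_weights,
                    train)
from gpdnet._layers import Network
from gpdnet.specs import (ConvLayerSpec, FireModuleSpec, GlobalAvgPoolSpec,
                          NetworkSpec, PoolLayerSpec, SoftmaxSpec)


class TestCrossEntropy:
    def test_closed_forms(self):
        assert cross_entropy_loss(np.full((1, 3), 1 / 3), [0]) == pytest.approx(
            math.log(3), abs=1e-9)
        exact = np.array([[0.0, 1.0, 0.0]])
        assert cross_entropy_loss(exact, [1]) == pytest.approx(0.0, abs=1e-12)
        two = np.array([[0.5, 0.3, 0.2], [0.25, 0.5, 0.25]])
        assert cross_entropy_loss(two, [0, 0]) == pytest.approx(
            -(math.log(0.5) + math.log(0.25)), abs=1e-9)

    def test_matches_per_sample_log_sum(self):
        """Batch loss equals a plain python per-sample -log sum."""
        rng = np.random.default_rng(0)
        raw = rng.random((100, 3))
        posteriors = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 3, 100)
        expected = sum(-math.log(posteriors[i, labels[i]]) for i in range(100))
        assert cross_entropy_loss(posteriors, labels) == pytest.approx(
            expected, abs=1e-9)

    def test_rejects_out_of_range_labels(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.full((2, 3), 1 / 3), [0, 3])

    def test_zero_probability_is_floored(self):
        loss = cross_entropy_loss(np.array([[1.0, 0.0, 0.0]]), [1])
        assert np.isfinite(loss) and loss == pytest.approx(-math.log(1e-12))


class TestBackpropagation:
    def test_gradients_match_finite_differences(self):
        """Analytic gradients of a small conv/fire/pool network agree with
        central differences in float64 (biases offset from zero so no ReLU
        pre-activation sits exactly on the kink)."""
        spec = NetworkSpec([
            ("conv1", ConvLayerSpec(3, 4, 3, padding=1)),
            ("pool1", PoolLayerSpec("max")),
            ("fire2", FireModuleSpec(4, 2, 3, 3)),
            ("pool2", PoolLayerSpec("average")),
            ("conv3", ConvLayerSpec(6, 3, 1, relu=False)),
            ("gap", GlobalAvgPoolSpec()),
            ("prob", SoftmaxSpec()),
        ], num_classes=3, input_size=8)
        store = initialize_weights(spec, 5, dtype=np.float64)
        rng = np.random.default_rng(11)
        for key, arr in store.bias_items():
            arr += rng.normal(0.05, 0.02, arr.shape)
        x = np.random.default_rng(2).random((4, 3, 8, 8))
        y = np.array([0, 1, 2, 1])
        net = Network(spec, store.arrays)
        probs = net.forward(x, train=True)
        dlogits = probs.copy()
        dlogits[np.arange(4), y] -= 1.0
        grads = net.backward(dlogits)

        def loss():
            return cross_entropy_loss(net.forward(x), y)

        eps = 1e-6
        check_rng = np.random.default_rng(3)
        for key, arr in store.items():
            for _ in range(8):
                ix = tuple(check_rng.integers(0, s) for s in arr.shape)
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = loss()
                arr[ix] = orig - eps
                lm = loss()
                arr[ix] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key][ix] == pytest.approx(numeric, abs=1e-6), key


class TestTrain:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(base_lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(momentum=1.0)

    def test_single_epoch_history(self, fire_spec, tiny_split):
        train_set, _ = tiny_split
        result = train(fire_spec, train_set, TrainConfig(epochs=1, seed=0))
        assert len(result.history) == 1
        assert result.history.loss.iloc[0] >= 0
        assert np.isnan(result.history.accuracy.iloc[0])  # no test set given

    def test_seed_determinism_is_bit_exact(self, fire_spec, tiny_split):
        train_set, _ = tiny_split
        cfg = TrainConfig(epochs=2, seed=13)
        a = train(fire_spec, train_set, cfg)
        b = train(fire_spec, train_set, cfg)
        assert a.weights.equals(b.weights)
        assert (a.history.loss == b.history.loss).all()

    def test_init_shape_mismatch_rejected(self, fire_spec, baseline_spec,
                                          tiny_split):
        train_set, _ = tiny_split
        wrong = initialize_weights(baseline_spec, 0)
        with pytest.raises(ValueError):
            train(fire_spec, train_set, TrainConfig(epochs=1), init=wrong)

    def test_loss_decreases_on_easy_preset(self, easy_trained):
        """Smoothed (window 5) training loss is monotone decreasing."""
        _, history, _ = easy_trained
        smooth = history.loss.rolling(5).mean().dropna().to_numpy()
        assert (np.diff(smooth) < 0).all()

    def test_easy_preset_reaches_high_accuracy(self, easy_trained):
        _, history, _ = easy_trained
        assert history.accuracy.iloc[-1] > 0.9

    def test_resume_from_init_continues_not_restarts(self, fire_spec,
                                                     tiny_split):
        train_set, test_set = tiny_split
        first = train(fire_spec, train_set, TrainConfig(epochs=2, seed=3))
        resumed = train(fire_spec, train_set, TrainConfig(epochs=1, seed=4),
                        init=first.weights)
        fresh = train(fire_spec, train_set, TrainConfig(epochs=1, seed=4))
        assert not resumed.weights.equals(fresh.weights)
        assert resumed.history.loss.iloc[0] <= fresh.history.loss.iloc[0] * 1.1


class TestEvaluate:
    def _uniform_store(self, spec):
        template = initialize_weights(spec, 0)
        return WeightStore({k: np.zeros_like(v) for k, v in template.items()})

    def test_all_correct_is_one(self, fire_spec, easy_trained):
        weights, _, test_set = easy_trained
        correct = evaluate_accuracy(fire_spec, weights, test_set)
        assert 0.9 < correct <= 1.0

    def test_uniform_posterior_ties_break_to_class_zero(self, fire_spec):
        rng = np.random.default_rng(0)
        images = rng.random((10, 32, 32, 3)).astype(np.float32)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2])  # 40% class 0
        test_set = LabeledImageSet(images, labels)
        acc = evaluate_accuracy(fire_spec, self._uniform_store(fire_spec), test_set)
        assert acc == pytest.approx(0.40)

    def test_label_permutation_never_exceeds_identity(self, fire_spec,
                                                      easy_trained):
        weights, _, test_set = easy_trained
        permuted = LabeledImageSet(test_set.images, (test_set.labels + 1) % 3)
        acc = evaluate_accuracy(fire_spec, weights, test_set)
        assert evaluate_accuracy(fire_spec, weights, permuted) <= acc
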