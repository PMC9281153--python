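"""Loss, LR schedule, clipping, SGD update, training loop, gradient check."""

import math

import numpy as np
import pytest

from scdlc.features import select_top_genes
from scdlc.network import forward_batch, init_params
from scdlc.simulate import ConfigurationError, SimulationConfig, simulate_counts
from scdlc.training import (
    LrSchedule,
    TrainConfig,
    clip_gradients,
    cross_entropy_loss,
    decayed_learning_rate,
    gradient_check,
    loss_and_gradients,
    mbgd_update,
    train_model,
)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert cross_entropy_loss(probs, np.array([0, 1, 2])) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_is_log_m(self):
        probs = np.full((5, 4), 0.25)
        assert cross_entropy_loss(probs, np.zeros(5, dtype=int)) == pytest.approx(math.log(4))

    def test_two_sample_worked_example(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = -(math.log(0.9) + math.log(0.8)) / 2
        assert cross_entropy_loss(probs, np.array([0, 1])) == pytest.approx(expected, rel=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.empty((0, 2)), np.array([], dtype=int))


class TestLrSchedule:
    def test_starts_at_max_lr(self):
        sched = LrSchedule(0.005, 0.001, total_steps=200)
        assert decayed_learning_rate(sched, 0) == 0.005

    def test_ends_at_min_lr(self):
        sched = LrSchedule(0.005, 0.001, total_steps=200)
        assert decayed_learning_rate(sched, 200) == pytest.approx(0.001, abs=1e-9)

    def test_midpoint_is_geometric_mean(self):
        sched = LrSchedule(0.005, 0.001, total_steps=200)
        assert decayed_learning_rate(sched, 100) == pytest.approx(
            math.sqrt(0.005 * 0.001), rel=1e-12
        )

    def test_floored_beyond_total_steps(self):
        sched = LrSchedule(0.005, 0.001, total_steps=100)
        assert decayed_learning_rate(sched, 1000) == 0.001

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            decayed_learning_rate(LrSchedule(0.005, 0.001, 10), -1)


class TestClipGradients:
    def test_below_threshold_unchanged(self):
        grads = {"w": np.array([1.0, 1.0]), "b": np.array([1.0, 1.0])}  # norm 2
        out = clip_gradients(grads, 5.0)
        assert out is grads

    def test_boundary_norm_unchanged(self):
        grads = {"w": np.array([3.0, 4.0])}
        out = clip_gradients(grads, 5.0)
        np.testing.assert_array_equal(out["w"], [3.0, 4.0])

    def test_rescales_above_threshold(self):
        grads = {"w": np.array([6.0, 8.0])}
        out = clip_gradients(grads, 5.0)
        np.testing.assert_allclose(out["w"], [3.0, 4.0], rtol=1e-12)

    def test_global_norm_spans_arrays(self):
        grads = {"a": np.array([6.0]), "b": np.array([8.0])}
        out = clip_gradients(grads, 5.0)
        np.testing.assert_allclose(out["a"], [3.0], rtol=1e-12)
        np.testing.assert_allclose(out["b"], [4.0], rtol=1e-12)


class TestMbgdUpdate:
    def test_zero_gradients_are_fixed_point(self):
        params = init_params(2, hidden_size=3, seed=0)
        before = {k: v.copy() for k, v in params.to_dict().items()}
        zeros = {k: np.zeros_like(v) for k, v in before.items()}
        mbgd_update(params, zeros, 0.1)
        for k, v in params.to_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_zero_learning_rate_is_null_step(self):
        params = init_params(2, hidden_size=3, seed=0)
        before = {k: v.copy() for k, v in params.to_dict().items()}
        grads = {k: np.ones_like(v) for k, v in before.items()}
        mbgd_update(params, grads, 0.0)
        for k, v in params.to_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_scalar_arithmetic(self):
        params = init_params(2, hidden_size=3, seed=0)
        params.fc2_b[:] = 1.0
        grads = {k: np.zeros_like(v) for k, v in params.to_dict().items()}
        grads["fc2_b"][:] = 2.0
        mbgd_update(params, grads, 0.1)
        np.testing.assert_allclose(params.fc2_b, 0.8, rtol=1e-12)


def _small_training_problem(n_per_class=22, g=30, de=0.6, seed=0):
    cfg = SimulationConfig(2, (n_per_class, n_per_class), g, de, 0.1, seed=seed)
    matrix, labels = simulate_counts(cfg)
    ranking = select_top_genes(matrix, labels, p=10)
    return matrix, labels, ranking


class TestTrainModel:
    def test_zero_epochs_returns_seeded_init(self):
        matrix, labels, ranking = _small_training_problem()
        cfg = TrainConfig(hidden_size=4, embed_dim=4, epochs=0, seed=3)
        params, report = train_model(matrix, labels, ranking, cfg)
        init = init_params(2, hidden_size=4, embed_dim=4, seed=3,
                           fc1_mode="dense", n_features=ranking.p)
        for k, v in params.to_dict().items():
            np.testing.assert_array_equal(v, init.to_dict()[k])
        assert report.losses == []

    def test_first_loss_near_log_k(self):
        # with near-symmetric init the pre-training prediction is close to
        # uniform; averaged over seeds the first batch loss is ~ log K
        matrix, labels, ranking = _small_training_problem()
        first = []
        for seed in range(8):
            cfg = TrainConfig(hidden_size=8, embed_dim=8, epochs=1, seed=seed)
            _, report = train_model(matrix, labels, ranking, cfg)
            first.append(report.losses[0])
        assert np.mean(first) == pytest.approx(math.log(2), rel=0.1)

    def test_training_is_reproducible(self):
        matrix, labels, ranking = _small_training_problem()
        cfg = TrainConfig(hidden_size=4, embed_dim=4, epochs=2, seed=9)
        p1, r1 = train_model(matrix, labels, ranking, cfg)
        p2, r2 = train_model(matrix, labels, ranking, cfg)
        for k, v in p1.to_dict().items():
            np.testing.assert_array_equal(v, p2.to_dict()[k])
        assert r1.losses == r2.losses

    def test_lr_trajectory_matches_closed_form(self):
        matrix, labels, ranking = _small_training_problem()
        cfg = TrainConfig(hidden_size=4, embed_dim=4, epochs=3, seed=2)
        _, report = train_model(matrix, labels, ranking, cfg)
        total = report.total_steps
        r = math.log(cfg.max_lr / cfg.min_lr) / total
        for s, lr in enumerate(report.learning_rates):
            assert lr == pytest.approx(max(cfg.min_lr, cfg.max_lr * math.exp(-r * s)),
                                       abs=1e-15)
        assert report.learning_rates[0] == 0.005
        assert report.learning_rates[-1] == pytest.approx(0.001, abs=1e-9)
        assert len(report.learning_rates) == total + 1
        # non-increasing, bounded
        diffs = np.diff(report.learning_rates)
        assert np.all(diffs <= 1e-15)

    def test_single_batch_mode_warns(self):
        matrix, labels, ranking = _small_training_problem(n_per_class=4)
        cfg = TrainConfig(hidden_size=3, embed_dim=3, epochs=1, batch_size=64, seed=0)
        with pytest.warns(UserWarning, match="single-batch"):
            train_model(matrix, labels, ranking, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(min_lr=0.01, max_lr=0.005)
        with pytest.raises(ConfigurationError):
            TrainConfig(keep_prob=0.0)
        with pytest.raises(ConfigurationError):
            TrainConfig(grad_clip=-1.0)


class TestGradientCheck:
    def test_tiny_model_passes(self):
        rng = np.random.default_rng(4)
        params = init_params(n_classes=2, hidden_size=3, embed_dim=3, seed=5)
        X = rng.normal(size=(5, 4))
        y = rng.integers(0, 2, size=5)
        report = gradient_check(params, X, y, tolerance=1e-4)
        assert report.passed
        assert report.max_rel_error < 1e-4

    def test_corrupted_gradient_fails_naming_weight(self):
        rng = np.random.default_rng(4)
        params = init_params(n_classes=2, hidden_size=3, embed_dim=3, seed=5)
        X = rng.normal(size=(5, 4))
        y = rng.integers(0, 2, size=5)
        _, grads = loss_and_gradients(params, X, y)
        grads["lstm1_W_i"][0, 0] += 1.0
        report = gradient_check(params, X, y, tolerance=1e-4, gradients=grads)
        assert not report.passed
        assert report.worst_parameter == "lstm1_W_i"

    def test_empty_batch_rejected(self):
        params = init_params(n_classes=2, hidden_size=3, seed=0)
        with pytest.raises(ValueError):
            gradient_check(params, np.empty((0, 4)), np.array([], dtype=int))

    def test_dropout_gradients_with_fixed_masks(self):
        """Analytic dropout-path gradients agree with finite differences
        when the same masks are replayed (identical rng seed)."""
        rng = np.random.default_rng(12)
        params = init_params(n_classes=2, hidden_size=3, embed_dim=3, seed=6)
        X = rng.normal(size=(4, 3))
        y = rng.integers(0, 2, size=4)

        def loss_with_masks(p):
            drng = np.random.default_rng(77)
            probs = forward_batch(X, p, keep_prob=0.5, training=True, rng=drng)
            return cross_entropy_loss(probs, y)

        _, grads = loss_and_gradients(params, X, y, keep_prob=0.5, training=True,
                                      rng=np.random.default_rng(77))
        arrays = params.to_dict()
        for name in ("fc1_W", "lstm1_W_C", "lstm2_W_o", "fc2_W"):
            arr = arrays[name].reshape(-1)
            g = grads[name].reshape(-1)
            for j in (0, arr.size // 2):
                orig = arr[j]
                arr[j] = orig + 1e-6
                lp = loss_with_masks(params)
                arr[j] = orig - 1e-6
                lm = loss_with_masks(params)
                arr[j] = orig
                fd = (lp - lm) / 2e-6
                assert fd == pytest.approx(g[j], rel=1e-3, abs=1e-9), name
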