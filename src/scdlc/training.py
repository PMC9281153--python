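"""Training: mini-batch gradient descent on the cross-entropy loss.

The gradients of the network are computed analytically (backpropagation
through time over both LSTM sublayers and the two fully connected
layers); ``gradient_check`` validates them against central finite
differences. The optimizer is plain SGD with global-norm gradient
clipping and an exponentially decaying learning rate

    eta(s) = max_lr * exp(-r * s),   r = log(max_lr / min_lr) / total_steps,

which starts at ``max_lr`` at global step s = 0 and reaches ``min_lr``
exactly at the final step; it is floored at ``min_lr`` thereafter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureRanking
from .network import ScdlcParams, forward_batch, init_params, prepare_inputs
from .simulate import ClassLabels, ConfigurationError, CountMatrix

__all__ = [
    "TrainConfig",
    "LrSchedule",
    "TrainReport",
    "cross_entropy_loss",
    "decayed_learning_rate",
    "clip_gradients",
    "mbgd_update",
    "train_model",
    "gradient_check",
    "loss_and_gradients",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the scDLC training recipe.

    Defaults are the published settings: hidden state of size 64, batches
    of 11 samples, gradient-norm threshold 5, dropout keep probability
    0.3, and a learning rate decaying exponentially from 0.005 to 0.001.
    """

    hidden_size: int = 64
    batch_size: int = 11
    grad_clip: float = 5.0
    keep_prob: float = 0.3
    max_lr: float = 0.005
    min_lr: float = 0.001
    epochs: int = 100
    seed: int = 0
    embed_dim: int | None = None  # fc1 per-timestep width; None -> hidden_size
    fc1_mode: str = "dense"       # 'dense' (whole-vector fc1) or 'timestep'

    def __post_init__(self) -> None:
        if not 0 < self.min_lr <= self.max_lr:
            raise ConfigurationError(f"need 0 < min_lr <= max_lr, got {self.min_lr}, {self.max_lr}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if not 0 < self.keep_prob <= 1:
            raise ConfigurationError(f"keep_prob must be in (0,1], got {self.keep_prob}")
        if self.grad_clip <= 0:
            raise ConfigurationError(f"grad_clip must be positive, got {self.grad_clip}")
        if self.epochs < 0:
            raise ConfigurationError(f"epochs must be >= 0, got {self.epochs}")
        if self.fc1_mode not in ("dense", "timestep"):
            raise ConfigurationError(f"unknown fc1_mode {self.fc1_mode!r}")


@dataclass(frozen=True)
class LrSchedule:
    """Exponential decay schedule; ``total_steps`` = epochs * batches/epoch."""

    max_lr: float
    min_lr: float
    total_steps: int

    @property
    def decay_rate(self) -> float:
        if self.total_steps == 0:
            return 0.0
        return math.log(self.max_lr / self.min_lr) / self.total_steps


def decayed_learning_rate(schedule: LrSchedule, step: int) -> float:
    """eta(s) = max_lr * exp(-r*s), floored at min_lr; s must be >= 0."""
    if step < 0:
        raise ValueError(f"global step must be >= 0, got {step}")
    lr = schedule.max_lr * math.exp(-schedule.decay_rate * step)
    return max(schedule.min_lr, lr)


@dataclass
class TrainReport:
    """Per-step training trajectories and summary metadata."""

    losses: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    final_train_accuracy: float = float("nan")
    epochs_run: int = 0
    seed: int = 0
    total_steps: int = 0


def cross_entropy_loss(predicted_probs: np.ndarray, true_labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class (natural log).

    ``true_labels`` are 0-based class codes; probabilities are floored at
    1e-12 before the log.
    """
    probs = np.atleast_2d(np.asarray(predicted_probs, dtype=np.float64))
    labels = np.asarray(true_labels, dtype=np.int64)
    n = probs.shape[0]
    if n == 0:
        raise ValueError("cross entropy of zero samples")
    if labels.shape != (n,):
        raise ValueError(f"{labels.shape[0] if labels.ndim else 0} labels for {n} rows")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label code outside 0..M-1")
    picked = np.maximum(probs[np.arange(n), labels], _PROB_FLOOR)
    return float(-np.mean(np.log(picked)))


def clip_gradients(gradients: dict[str, np.ndarray], threshold: float) -> dict[str, np.ndarray]:
    """Global-norm clipping: rescale all gradients if their joint L2 norm
    exceeds ``threshold``; otherwise return them unchanged."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    total = math.sqrt(sum(float(np.sum(g * g)) for g in gradients.values()))
    if total <= threshold or total == 0.0:
        return gradients
    scale = threshold / total
    return {k: g * scale for k, g in gradients.items()}


def mbgd_update(params: ScdlcParams, gradients: dict[str, np.ndarray], learning_rate: float) -> ScdlcParams:
    """Plain SGD step theta <- theta - eta * dL/dtheta, in place."""
    arrays = params.to_dict()
    if set(arrays) != set(gradients):
        raise ValueError("gradient keys do not match parameter keys")
    for name, arr in arrays.items():
        g = gradients[name]
        if g.shape != arr.shape:
            raise ValueError(f"gradient shape {g.shape} != parameter shape {arr.shape} for {name}")
        arr -= learning_rate * g
    return params


def _sigmoid_deriv(s: np.ndarray) -> np.ndarray:
    return s * (1.0 - s)


def loss_and_gradients(
    params: ScdlcParams,
    X: np.ndarray,
    y: np.ndarray,
    keep_prob: float = 1.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy loss and its analytic gradients for one batch.

    Backpropagation through time over both LSTM sublayers; gradients are
    returned as a flat name -> array dict matching ``params.to_dict()``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    n, p = X.shape
    if n == 0:
        raise ValueError("empty batch")
    H = params.hidden_size
    use_dropout = training and keep_prob < 1.0

    probs, cache = forward_batch(
        X, params, keep_prob=keep_prob, training=training, rng=rng, return_cache=True
    )
    loss = cross_entropy_loss(probs, y)

    Ws1, _ = params.lstm1.stacked()
    Ws2, _ = params.lstm2.stacked()
    W1h, W1x = Ws1[:, :H], Ws1[:, H:]
    W2h, W2x = Ws2[:, :H], Ws2[:, H:]
    D = params.embed_dim

    # softmax + cross-entropy combined gradient
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    grads = {k: np.zeros_like(v) for k, v in params.to_dict().items()}
    grads["fc2_W"] += dlogits.T @ cache["h2_out"]
    grads["fc2_b"] += dlogits.sum(axis=0)

    dh2_readout = dlogits @ params.fc2_W
    if use_dropout:
        dh2_readout = dh2_readout * cache["mask2"]

    G1, G2 = cache["G1"], cache["G2"]
    C1s, C2s = cache["C1"], cache["C2"]
    T1s, T2s = cache["T1"], cache["T2"]
    M1 = cache["mask1"]

    # per-step gate-preactivation gradients, stacked for bulk weight grads
    DP1 = np.empty((p, n, 4 * H))
    DP2 = np.empty((p, n, 4 * H))

    dh1_rec = np.zeros((n, H)); dC1_rec = np.zeros((n, H))
    dh2_rec = np.zeros((n, H)); dC2_rec = np.zeros((n, H))
    zeros_nh = np.zeros((n, H))

    for t in range(p - 1, -1, -1):
        # ---- sublayer 2 ----
        dh2 = (dh2_rec + dh2_readout) if t == p - 1 else dh2_rec
        g2 = G2[t]
        f2, i2, ct2, o2 = g2[:, :H], g2[:, H:2 * H], g2[:, 2 * H:3 * H], g2[:, 3 * H:]
        tanhC2 = T2s[t]
        C2_prev = C2s[t - 1] if t > 0 else zeros_nh
        do2 = dh2 * tanhC2
        dC2 = dC2_rec + dh2 * o2 * (1.0 - tanhC2 ** 2)
        dpre2 = DP2[t]
        dpre2[:, :H] = dC2 * C2_prev * _sigmoid_deriv(f2)
        dpre2[:, H:2 * H] = dC2 * ct2 * _sigmoid_deriv(i2)
        dpre2[:, 2 * H:3 * H] = dC2 * i2 * (1.0 - ct2 ** 2)
        dpre2[:, 3 * H:] = do2 * _sigmoid_deriv(o2)
        dC2_rec = dC2 * f2
        dh2_rec = dpre2 @ W2h
        dh1_above = dpre2 @ W2x
        if use_dropout:
            dh1_above = dh1_above * M1[t]

        # ---- sublayer 1 ----
        dh1 = dh1_rec + dh1_above
        g1 = G1[t]
        f1, i1, ct1, o1 = g1[:, :H], g1[:, H:2 * H], g1[:, 2 * H:3 * H], g1[:, 3 * H:]
        tanhC1 = T1s[t]
        C1_prev = C1s[t - 1] if t > 0 else zeros_nh
        do1 = dh1 * tanhC1
        dC1 = dC1_rec + dh1 * o1 * (1.0 - tanhC1 ** 2)
        dpre1 = DP1[t]
        dpre1[:, :H] = dC1 * C1_prev * _sigmoid_deriv(f1)
        dpre1[:, H:2 * H] = dC1 * ct1 * _sigmoid_deriv(i1)
        dpre1[:, 2 * H:3 * H] = dC1 * i1 * (1.0 - ct1 ** 2)
        dpre1[:, 3 * H:] = do1 * _sigmoid_deriv(o1)
        dC1_rec = dC1 * f1
        dh1_rec = dpre1 @ W1h

    # ---- bulk weight/bias gradients over all timesteps ----
    A = cache["A"]  # (p, n, D)
    # z1 = [h1_{t-1}, a_t]; z2 = [h2_{t-1}, h1out_t]
    H1_prev = np.concatenate([zeros_nh[None], cache["H1"][:-1]])
    H2_prev = np.concatenate([zeros_nh[None], cache["H2"][:-1]])
    dp1 = DP1.reshape(p * n, 4 * H)
    dp2 = DP2.reshape(p * n, 4 * H)
    dWs1 = np.concatenate(
        [dp1.T @ H1_prev.reshape(p * n, H), dp1.T @ A.reshape(p * n, D)], axis=1
    )
    dWs2 = np.concatenate(
        [dp2.T @ H2_prev.reshape(p * n, H), dp2.T @ cache["H1out"].reshape(p * n, H)],
        axis=1,
    )
    dbs1 = dp1.sum(axis=0)
    dbs2 = dp2.sum(axis=0)

    # fc1: da -> relu mask -> input weights
    dA = (dp1 @ W1x).reshape(p, n, D)
    dzfc = dA * (A > 0)
    if params.fc1_mode == "timestep":
        grads["fc1_W"][:, 0] += np.einsum("pnd,np->d", dzfc, X, optimize=True)
        grads["fc1_b"] += dzfc.sum(axis=(0, 1))
    else:
        dAflat = dzfc.transpose(1, 0, 2).reshape(n, p * D)
        grads["fc1_W"] += dAflat.T @ X
        grads["fc1_b"] += dAflat.sum(axis=0)

    for tag, dW, db in (("lstm1", dWs1, dbs1), ("lstm2", dWs2, dbs2)):
        for gi, gate in enumerate(("f", "i", "C", "o")):
            grads[f"{tag}_W_{gate}"] += dW[gi * H:(gi + 1) * H]
            grads[f"{tag}_b_{gate}"] += db[gi * H:(gi + 1) * H]
    return loss, grads


def _stream_rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def train_model(
    train_counts: CountMatrix,
    train_labels: ClassLabels,
    ranking: FeatureRanking,
    config: TrainConfig,
) -> tuple[ScdlcParams, TrainReport]:
    """Fit the classifier by mini-batch gradient descent.

    Per epoch: seeded shuffle, consecutive batches of ``batch_size`` (the
    last short batch is trained on, not dropped); per batch: forward with
    dropout, cross-entropy, backpropagation, global-norm clipping, SGD
    update at the decayed learning rate, incrementing the global step.
    The logged learning-rate trajectory has ``total_steps + 1`` entries:
    the rate used at each step plus the final rate after training.
    """
    X = prepare_inputs(train_counts, ranking.selected)
    y = train_labels.labels
    n = X.shape[0]
    M = train_labels.n_classes

    params = init_params(
        n_classes=M,
        hidden_size=config.hidden_size,
        embed_dim=config.embed_dim,
        seed=config.seed,
        fc1_mode=config.fc1_mode,
        n_features=X.shape[1],
    )
    if n < config.batch_size:
        warnings.warn(
            f"{n} training samples < batch size {config.batch_size}; "
            "running in single-batch mode", stacklevel=2,
        )
    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    schedule = LrSchedule(config.max_lr, config.min_lr, total_steps)

    shuffle_rng = _stream_rng(config.seed, 201)
    dropout_rng = _stream_rng(config.seed, 202)

    report = TrainReport(seed=config.seed, total_steps=total_steps)
    step = 0
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            lr = decayed_learning_rate(schedule, step)
            loss, grads = loss_and_gradients(
                params, X[idx], y[idx],
                keep_prob=config.keep_prob, training=True, rng=dropout_rng,
            )
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at step {step} (epoch {_epoch}); "
                    "check learning rate / input scale"
                )
            grads = clip_gradients(grads, config.grad_clip)
            mbgd_update(params, grads, lr)
            report.losses.append(loss)
            report.learning_rates.append(lr)
            step += 1
        report.epochs_run = _epoch + 1
    report.learning_rates.append(decayed_learning_rate(schedule, step))

    probs = forward_batch(X, params)
    report.final_train_accuracy = float(np.mean(np.argmax(probs, axis=1) == y))
    return params, report


@dataclass
class GradientCheckReport:
    passed: bool
    max_rel_error: float
    worst_parameter: str
    tolerance: float
    per_parameter: dict[str, float]


def gradient_check(
    params: ScdlcParams,
    X: np.ndarray,
    y: np.ndarray,
    tolerance: float = 1e-4,
    step: float = 1e-5,
    gradients: dict[str, np.ndarray] | None = None,
) -> GradientCheckReport:
    """Compare analytic gradients with central finite differences.

    Intended for tiny models (a few hundred parameters). Dropout is
    disabled (keep_prob = 1) so the loss is deterministic. If
    ``gradients`` is given it is checked instead of freshly computed
    ones (useful as a negative control).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.int64)
    if X.shape[0] == 0:
        raise ValueError("empty batch")

    if gradients is None:
        _, gradients = loss_and_gradients(params, X, y)

    arrays = params.to_dict()
    per_param: dict[str, float] = {}
    worst = ("", 0.0)
    for name, arr in arrays.items():
        analytic = gradients[name]
        rel_max = 0.0
        flat = arr.reshape(-1)
        aflat = analytic.reshape(-1)
        for j in range(flat.size):
            orig = flat[j]
            flat[j] = orig + step
            lp = cross_entropy_loss(forward_batch(X, params), y)
            flat[j] = orig - step
            lm = cross_entropy_loss(forward_batch(X, params), y)
            flat[j] = orig
            fd = (lp - lm) / (2 * step)
            denom = max(abs(fd) + abs(aflat[j]), 1e-8)
            rel = abs(fd - aflat[j]) / denom
            rel_max = max(rel_max, rel)
        per_param[name] = rel_max
        if rel_max > worst[1]:
            worst = (name, rel_max)
    passed = worst[1] <= tolerance
    return GradientCheckReport(
        passed=passed,
        max_rel_error=worst[1],
        worst_parameter=worst[0] if not passed else "",
        tolerance=tolerance,
        per_parameter=per_param,
    )
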