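"""Replicate-parallel training for simulation-study harnesses.

Simulation studies train many independent replicates of the same
architecture on same-shaped datasets. Training them one at a time wastes
most of the wall clock on per-timestep overhead at mini-batch size 11,
so this module stacks R replicates along a leading axis and runs every
step as batched matrix products.

The parallel path is *defined* to reproduce ``training.train_model``
replicate by replicate: per-replicate shuffle and dropout generators use
the same named streams and draw in the same order, so the resulting
parameters agree with the sequential trainer to floating-point roundoff.
An equivalence test enforces this; the sequential path is the one
validated by the finite-difference gradient check.
"""

from __future__ import annotations

import math

import numpy as np

from .network import ScdlcParams, _sigmoid, from_dict, init_params
from .training import LrSchedule, TrainConfig, TrainReport, decayed_learning_rate

__all__ = ["train_models_parallel", "forward_parallel", "predict_parallel"]


def _softmax(y: np.ndarray) -> np.ndarray:
    """Stable softmax along the last axis, preserving dtype."""
    shifted = y - y.max(axis=-1, keepdims=True)
    np.exp(shifted, out=shifted)
    shifted /= shifted.sum(axis=-1, keepdims=True)
    return shifted


_ALLOCATOR_TUNED = False


def _tune_allocator() -> None:
    """Raise glibc's mmap threshold so the multi-megabyte temporaries of
    the batched passes are served from the reusable heap instead of
    fresh mmap/munmap cycles (which page-fault on every step).

    No-op on non-glibc platforms."""
    global _ALLOCATOR_TUNED
    if _ALLOCATOR_TUNED:
        return
    _ALLOCATOR_TUNED = True
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6", use_errno=True)
        M_MMAP_THRESHOLD = -3
        libc.mallopt(M_MMAP_THRESHOLD, 1 << 30)
    except Exception:
        pass


def _stack_params(params_list: list[ScdlcParams]) -> dict[str, np.ndarray]:
    keys = params_list[0].to_dict().keys()
    return {k: np.stack([p.to_dict()[k] for p in params_list]) for k in keys}


def _unstack_params(stack: dict[str, np.ndarray], r: int) -> ScdlcParams:
    return from_dict({k: v[r].astype(np.float64) for k, v in stack.items()})


def _weights(stack: dict[str, np.ndarray]):
    """Contiguous per-pass weight blocks.

    Returns, per sublayer: stacked gate weights split into recurrent/input
    halves, both as (R, in, 4H) for the forward product and (R, 4H, in)
    for the backward product, plus stacked biases (R, 4H).
    """
    H = stack["fc2_W"].shape[2]
    out = {}
    for tag in ("lstm1", "lstm2"):
        W = np.concatenate([stack[f"{tag}_W_{g}"] for g in ("f", "i", "C", "o")], axis=1)
        b = np.concatenate([stack[f"{tag}_b_{g}"] for g in ("f", "i", "C", "o")], axis=1)
        Wh, Wx = W[:, :, :H], W[:, :, H:]
        out[tag] = {
            "WhT": np.ascontiguousarray(Wh.transpose(0, 2, 1)),  # (R, H, 4H)
            "WxT": np.ascontiguousarray(Wx.transpose(0, 2, 1)),  # (R, D, 4H)
            "Wh": np.ascontiguousarray(Wh),                      # (R, 4H, H)
            "Wx": np.ascontiguousarray(Wx),                      # (R, 4H, D)
            "b": b,
        }
    return out


def forward_parallel(
    X: np.ndarray,
    stack: dict[str, np.ndarray],
    keep_prob: float = 1.0,
    masks: tuple[np.ndarray, np.ndarray] | None = None,
    return_cache: bool = False,
):
    """Forward pass for R replicates at once. ``X``: (R, N, p).

    ``masks`` = (M1, m2) with shapes (R, p, N, H) and (R, N, H) enables
    training-mode dropout (inverted scaling already applied). All
    time-stacked intermediates use layout (R, p, N, units).
    """
    R, N, p = X.shape
    H = stack["fc2_W"].shape[2]
    fw = stack["fc1_W"]
    D = fw.shape[1] if fw.shape[2] == 1 else fw.shape[1] // fw.shape[2]
    dtype = stack["fc2_W"].dtype
    W = _weights(stack)
    use_dropout = masks is not None and keep_prob < 1.0
    M1, m2 = masks if use_dropout else (None, None)

    # fc1 embeddings for all timesteps: (R, p, N, D)
    if stack["fc1_W"].shape[2] == 1:  # shared per-timestep scalar embedding
        A = np.maximum(
            0.0,
            X.transpose(0, 2, 1)[:, :, :, None] * stack["fc1_W"][:, None, None, :, 0]
            + stack["fc1_b"][:, None, None, :],
        )
    else:  # dense whole-vector fc1, reshaped to the timestep sequence
        Aflat = np.maximum(
            0.0,
            np.matmul(X, stack["fc1_W"].transpose(0, 2, 1)) + stack["fc1_b"][:, None, :],
        )
        A = np.ascontiguousarray(
            Aflat.reshape(R, N, p, D).transpose(0, 2, 1, 3)
        )
    # input half of sublayer-1 preactivations, one gemm per replicate
    P1 = (np.matmul(A.reshape(R, p * N, D), W["lstm1"]["WxT"])
          .reshape(R, p, N, 4 * H) + W["lstm1"]["b"][:, None, None, :])

    h1 = np.zeros((R, N, H), dtype); C1 = np.zeros((R, N, H), dtype)
    h2 = np.zeros((R, N, H), dtype); C2 = np.zeros((R, N, H), dtype)
    b2 = W["lstm2"]["b"][:, None, :]

    if return_cache:
        G1 = np.empty((R, p, N, 4 * H), dtype); G2 = np.empty((R, p, N, 4 * H), dtype)
        C1s = np.empty((R, p, N, H), dtype); C2s = np.empty((R, p, N, H), dtype)
        T1s = np.empty((R, p, N, H), dtype); T2s = np.empty((R, p, N, H), dtype)
        H1s = np.empty((R, p, N, H), dtype); H2s = np.empty((R, p, N, H), dtype)
        H1out = np.empty((R, p, N, H), dtype)

    for t in range(p):
        pre1 = np.matmul(h1, W["lstm1"]["WhT"]) + P1[:, t]
        g1 = _sigmoid(pre1)
        ct1 = np.tanh(pre1[:, :, 2 * H:3 * H])
        f1, i1, o1 = g1[:, :, :H], g1[:, :, H:2 * H], g1[:, :, 3 * H:]
        C1 = f1 * C1 + i1 * ct1
        tanhC1 = np.tanh(C1)
        h1 = o1 * tanhC1
        h1_out = h1 * M1[:, t] if use_dropout else h1

        pre2 = np.matmul(h2, W["lstm2"]["WhT"]) + np.matmul(h1_out, W["lstm2"]["WxT"]) + b2
        g2 = _sigmoid(pre2)
        ct2 = np.tanh(pre2[:, :, 2 * H:3 * H])
        f2, i2, o2 = g2[:, :, :H], g2[:, :, H:2 * H], g2[:, :, 3 * H:]
        C2 = f2 * C2 + i2 * ct2
        tanhC2 = np.tanh(C2)
        h2 = o2 * tanhC2

        if return_cache:
            G1[:, t] = g1; G1[:, t, :, 2 * H:3 * H] = ct1
            G2[:, t] = g2; G2[:, t, :, 2 * H:3 * H] = ct2
            C1s[:, t] = C1; C2s[:, t] = C2; T1s[:, t] = tanhC1; T2s[:, t] = tanhC2
            H1s[:, t] = h1; H2s[:, t] = h2; H1out[:, t] = h1_out

    h2_out = h2 * m2 if use_dropout else h2
    logits = np.matmul(h2_out, stack["fc2_W"].transpose(0, 2, 1)) + stack["fc2_b"][:, None, :]
    probs = _softmax(logits)
    if not return_cache:
        return probs
    cache = {
        "A": A, "G1": G1, "G2": G2, "C1": C1s, "C2": C2s, "T1": T1s, "T2": T2s,
        "H1": H1s, "H2": H2s, "H1out": H1out, "M1": M1, "m2": m2,
        "h2_out": h2_out, "probs": probs, "W": W,
    }
    return probs, cache


def predict_parallel(
    X: np.ndarray,
    stack: dict[str, np.ndarray],
    chunk: int = 64,
) -> np.ndarray:
    """Memory-bounded inference over many cells for R replicates.

    ``forward_parallel`` precomputes every timestep's input projection at
    once, which is O(R * N * p * 4H) memory; evaluating hundreds of cells
    per replicate in one call would need gigabytes. This wrapper chunks
    the cell axis.
    """
    outs = [
        forward_parallel(np.ascontiguousarray(X[:, start:start + chunk]), stack)
        for start in range(0, X.shape[1], chunk)
    ]
    return np.concatenate(outs, axis=1)


def _sigmoid_deriv(s: np.ndarray) -> np.ndarray:
    return s * (1.0 - s)


def _losses_and_grads_parallel(
    stack: dict[str, np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    keep_prob: float,
    masks: tuple[np.ndarray, np.ndarray] | None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-replicate cross-entropy losses and stacked gradients.

    ``X``: (R, N, p); ``y``: (R, N). Mirrors the sequential
    backpropagation in ``training.loss_and_gradients``.
    """
    R, N, p = X.shape
    H = stack["fc2_W"].shape[2]
    fw = stack["fc1_W"]
    D = fw.shape[1] if fw.shape[2] == 1 else fw.shape[1] // fw.shape[2]
    use_dropout = masks is not None and keep_prob < 1.0

    probs, cache = forward_parallel(X, stack, keep_prob, masks if use_dropout else None,
                                    return_cache=True)
    r_idx = np.arange(R)[:, None]
    n_idx = np.arange(N)[None, :]
    picked = np.maximum(probs[r_idx, n_idx, y], 1e-12)
    losses = -np.mean(np.log(picked), axis=1)  # (R,)

    dlogits = probs.copy()
    dlogits[r_idx, n_idx, y] -= 1.0
    dlogits /= N

    grads = {}
    grads["fc2_W"] = np.matmul(dlogits.transpose(0, 2, 1), cache["h2_out"])
    grads["fc2_b"] = dlogits.sum(axis=1)

    dh2_readout = np.matmul(dlogits, stack["fc2_W"])
    if use_dropout:
        dh2_readout = dh2_readout * cache["m2"]

    W = cache["W"]
    G1, G2 = cache["G1"], cache["G2"]
    C1s, C2s = cache["C1"], cache["C2"]
    T1s, T2s = cache["T1"], cache["T2"]
    M1 = cache["M1"]

    dtype = stack["fc2_W"].dtype
    DP1 = np.empty((R, p, N, 4 * H), dtype)
    DP2 = np.empty((R, p, N, 4 * H), dtype)
    zeros = np.zeros((R, N, H), dtype)
    dh1_rec = zeros.copy(); dC1_rec = zeros.copy()
    dh2_rec = zeros.copy(); dC2_rec = zeros.copy()

    for t in range(p - 1, -1, -1):
        dh2 = (dh2_rec + dh2_readout) if t == p - 1 else dh2_rec
        g2 = G2[:, t]
        f2, i2, ct2, o2 = (g2[:, :, :H], g2[:, :, H:2 * H],
                           g2[:, :, 2 * H:3 * H], g2[:, :, 3 * H:])
        tanhC2 = T2s[:, t]
        C2_prev = C2s[:, t - 1] if t > 0 else zeros
        do2 = dh2 * tanhC2
        dC2 = dC2_rec + dh2 * o2 * (1.0 - tanhC2 ** 2)
        dpre2 = DP2[:, t]
        dpre2[:, :, :H] = dC2 * C2_prev * _sigmoid_deriv(f2)
        dpre2[:, :, H:2 * H] = dC2 * ct2 * _sigmoid_deriv(i2)
        dpre2[:, :, 2 * H:3 * H] = dC2 * i2 * (1.0 - ct2 ** 2)
        dpre2[:, :, 3 * H:] = do2 * _sigmoid_deriv(o2)
        dC2_rec = dC2 * f2
        dh2_rec = np.matmul(dpre2, W["lstm2"]["Wh"])
        dh1_above = np.matmul(dpre2, W["lstm2"]["Wx"])
        if use_dropout:
            dh1_above = dh1_above * M1[:, t]

        dh1 = dh1_rec + dh1_above
        g1 = G1[:, t]
        f1, i1, ct1, o1 = (g1[:, :, :H], g1[:, :, H:2 * H],
                           g1[:, :, 2 * H:3 * H], g1[:, :, 3 * H:])
        tanhC1 = T1s[:, t]
        C1_prev = C1s[:, t - 1] if t > 0 else zeros
        do1 = dh1 * tanhC1
        dC1 = dC1_rec + dh1 * o1 * (1.0 - tanhC1 ** 2)
        dpre1 = DP1[:, t]
        dpre1[:, :, :H] = dC1 * C1_prev * _sigmoid_deriv(f1)
        dpre1[:, :, H:2 * H] = dC1 * ct1 * _sigmoid_deriv(i1)
        dpre1[:, :, 2 * H:3 * H] = dC1 * i1 * (1.0 - ct1 ** 2)
        dpre1[:, :, 3 * H:] = do1 * _sigmoid_deriv(o1)
        dC1_rec = dC1 * f1
        dh1_rec = np.matmul(dpre1, W["lstm1"]["Wh"])

    A = cache["A"]
    H1_prev = np.concatenate([zeros[:, None], cache["H1"][:, :-1]], axis=1)
    H2_prev = np.concatenate([zeros[:, None], cache["H2"][:, :-1]], axis=1)
    dp1 = DP1.reshape(R, p * N, 4 * H)
    dp2 = DP2.reshape(R, p * N, 4 * H)
    dp1T = dp1.transpose(0, 2, 1)
    dp2T = dp2.transpose(0, 2, 1)
    dWs1 = np.concatenate(
        [np.matmul(dp1T, H1_prev.reshape(R, p * N, H)),
         np.matmul(dp1T, A.reshape(R, p * N, D))], axis=2
    )
    dWs2 = np.concatenate(
        [np.matmul(dp2T, H2_prev.reshape(R, p * N, H)),
         np.matmul(dp2T, cache["H1out"].reshape(R, p * N, H))], axis=2,
    )
    dbs1 = DP1.sum(axis=(1, 2))  # (R, 4H)
    dbs2 = DP2.sum(axis=(1, 2))

    dA = np.matmul(dp1, W["lstm1"]["Wx"]).reshape(R, p, N, D)
    dzfc = dA * (A > 0)
    if stack["fc1_W"].shape[2] == 1:
        grads["fc1_W"] = np.einsum("rpnd,rnp->rd", dzfc, X, optimize=True)[:, :, None]
        grads["fc1_b"] = dzfc.sum(axis=(1, 2))
    else:
        dAflat = np.ascontiguousarray(
            dzfc.transpose(0, 2, 1, 3)
        ).reshape(R, N, p * D)
        grads["fc1_W"] = np.matmul(dAflat.transpose(0, 2, 1), X)
        grads["fc1_b"] = dAflat.sum(axis=1)

    for tag, dW, db in (("lstm1", dWs1, dbs1), ("lstm2", dWs2, dbs2)):
        for gi, gate in enumerate(("f", "i", "C", "o")):
            grads[f"{tag}_W_{gate}"] = np.ascontiguousarray(dW[:, gi * H:(gi + 1) * H])
            grads[f"{tag}_b_{gate}"] = np.ascontiguousarray(db[:, gi * H:(gi + 1) * H])
    return losses, grads


def _stream_rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def train_models_parallel(
    Xs: np.ndarray,
    ys: np.ndarray,
    config: TrainConfig,
    seeds: list[int],
    dtype=np.float64,
) -> tuple[list[ScdlcParams], list[TrainReport]]:
    """Train R independent replicates simultaneously.

    ``Xs``: (R, n, p) preprocessed inputs; ``ys``: (R, n) label codes;
    ``seeds[r]`` plays the role of ``TrainConfig.seed`` for replicate r.
    All replicates share the architecture, hyperparameters and shapes.
    Replicate r's result matches ``train_model`` run with
    ``TrainConfig(..., seed=seeds[r])`` up to floating-point roundoff.

    ``dtype=np.float32`` halves memory traffic and roughly doubles
    throughput for large study harnesses; training remains deterministic
    for fixed seeds, but agreement with the float64 sequential path is
    then only statistical, not bitwise.
    """
    _tune_allocator()
    R, n, p = Xs.shape
    if len(seeds) != R:
        raise ValueError(f"{len(seeds)} seeds for {R} replicates")
    M = int(ys.max()) + 1
    Xs = np.asarray(Xs, dtype=dtype)
    stack = {
        k: v.astype(dtype, copy=False)
        for k, v in _stack_params([
            init_params(M, config.hidden_size, config.embed_dim, seed=s,
                        fc1_mode=config.fc1_mode, n_features=p)
            for s in seeds
        ]).items()
    }

    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    schedule = LrSchedule(config.max_lr, config.min_lr, total_steps)
    shuffle_rngs = [_stream_rng(s, 201) for s in seeds]
    dropout_rngs = [_stream_rng(s, 202) for s in seeds]
    use_dropout = config.keep_prob < 1.0
    H = config.hidden_size
    kp = config.keep_prob

    reports = [TrainReport(seed=s, total_steps=total_steps) for s in seeds]
    step = 0
    for _epoch in range(config.epochs):
        perms = np.stack([rng.permutation(n) for rng in shuffle_rngs])  # (R, n)
        for start in range(0, n, config.batch_size):
            idx = perms[:, start:start + config.batch_size]  # (R, b)
            b = idx.shape[1]
            Xb = Xs[np.arange(R)[:, None], idx]  # (R, b, p)
            yb = ys[np.arange(R)[:, None], idx]
            lr = decayed_learning_rate(schedule, step)
            masks = None
            if use_dropout:
                M1 = np.empty((R, p, b, H), dtype=dtype)
                m2 = np.empty((R, b, H), dtype=dtype)
                for r, rng in enumerate(dropout_rngs):
                    # same draw order as the sequential trainer: p per-step
                    # masks for sublayer 1, then the readout mask
                    M1[r] = (rng.random((p, b, H)) < kp) / kp
                    m2[r] = (rng.random((b, H)) < kp) / kp
                masks = (M1, m2)
            losses, grads = _losses_and_grads_parallel(stack, Xb, yb, kp, masks)
            if not np.all(np.isfinite(losses)):
                bad = int(np.flatnonzero(~np.isfinite(losses))[0])
                raise RuntimeError(f"non-finite loss in replicate {bad} at step {step}")
            # per-replicate global-norm clipping
            sq = np.zeros(R)
            for g in grads.values():
                sq += (g * g).sum(axis=tuple(range(1, g.ndim)), dtype=np.float64)
            norms = np.sqrt(sq)
            scale = np.where(norms > config.grad_clip,
                             config.grad_clip / np.maximum(norms, 1e-300), 1.0)
            for name, g in grads.items():
                stack[name] -= lr * g * scale.reshape((R,) + (1,) * (g.ndim - 1))
            for r in range(R):
                reports[r].losses.append(float(losses[r]))
                reports[r].learning_rates.append(lr)
            step += 1
        for r in range(R):
            reports[r].epochs_run = _epoch + 1
    final_lr = decayed_learning_rate(schedule, step)
    for r in range(R):
        reports[r].learning_rates.append(final_lr)

    probs = forward_parallel(Xs, stack)
    preds = np.argmax(probs, axis=2)
    params_list = []
    for r in range(R):
        reports[r].final_train_accuracy = float(np.mean(preds[r] == ys[r]))
        params_list.append(_unstack_params(stack, r))
    return params_list, reports
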