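"""The scDLC forward model.

Architecture: a first fully connected ReLU layer turns the p selected
gene expressions of a cell into a sequence of p timesteps (by default a
whole-vector map reshaped to p x embed_dim; alternatively a shared
per-timestep scalar embedding — see ``ScdlcParams``); two stacked LSTM
sublayers consume the sequence; a second fully connected layer maps the
final-timestep hidden state of the top sublayer to class scores; softmax
yields class probabilities.

Everything is plain NumPy. The training module differentiates this model
analytically (backpropagation through time); the forward pass therefore
optionally returns the caches backprop needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CountMatrix

__all__ = [
    "LstmLayerParams",
    "LstmState",
    "ScdlcParams",
    "fc_relu",
    "lstm_step",
    "softmax",
    "forward",
    "forward_batch",
    "predict",
    "log_normalize",
    "init_params",
    "save_params",
    "load_params",
]

CHECKPOINT_FORMAT_VERSION = 1


def _sigmoid(z):
    """Logistic function 1/(1+e^-z), evaluated via tanh for speed.

    0.5*(1+tanh(z/2)) is algebraically identical to the logistic form and
    uses the much faster vectorized tanh kernel. Preserves the input
    dtype.
    """
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z)))


def log_normalize(counts: np.ndarray) -> np.ndarray:
    """Library-size normalization to the median depth, then log(1+x).

    This is the expression scale fed to the network (and, by default, to
    the BW ranking): counts are scaled per cell so every cell has the
    median total count, then log1p-transformed. Cells with zero depth are
    left at zero depth (scale 1).
    """
    counts = np.asarray(counts, dtype=np.float64)
    depths = counts.sum(axis=0)
    median = np.median(depths)
    if median <= 0:
        return np.log1p(counts)
    safe = np.where(depths > 0, depths, 1.0)
    return np.log1p(counts * (median / safe)[None, :])


@dataclass
class LstmLayerParams:
    """Gate weights/biases of one LSTM sublayer.

    Each weight matrix acts on the concatenation [h_{t-1}, x_t] and has
    shape (hidden_size, hidden_size + input_size).
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shape = self.W_f.shape
        for name in ("W_i", "W_C", "W_o"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        h = shape[0]
        for name in ("b_f", "b_i", "b_C", "b_o"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} must have length {h}")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """Gate-stacked (4H, H+D) weight and (4H,) bias, order [f, i, C, o]."""
        W = np.concatenate([self.W_f, self.W_i, self.W_C, self.W_o], axis=0)
        b = np.concatenate([self.b_f, self.b_i, self.b_C, self.b_o])
        return W, b


@dataclass
class LstmState:
    """Hidden and cell state of one sublayer; h entries lie in (-1, 1)."""

    h: np.ndarray
    C: np.ndarray


@dataclass
class ScdlcParams:
    """All trainable weights and biases of the classifier.

    Two sequence constructions are supported, distinguished by the shape
    of ``fc1_W``:

    * dense (default): fc1 maps the whole p-gene expression vector to a
      p*embed_dim vector, reshaped to a sequence of p timesteps with
      embed_dim features each, so every timestep carries a learned mix of
      all genes. ``fc1_W`` has shape (p*embed_dim, p).
    * timestep: fc1 is a shared per-timestep map from one gene's scalar
      expression to an embed_dim vector; ``fc1_W`` has shape
      (embed_dim, 1) and the parameter count is independent of p.

    fc2 maps the final-timestep hidden state of the top LSTM sublayer to
    the M class scores.
    """

    fc1_W: np.ndarray
    fc1_b: np.ndarray
    lstm1: LstmLayerParams
    lstm2: LstmLayerParams
    fc2_W: np.ndarray  # (M, hidden)
    fc2_b: np.ndarray  # (M,)

    @property
    def hidden_size(self) -> int:
        return self.lstm1.hidden_size

    @property
    def fc1_mode(self) -> str:
        return "timestep" if self.fc1_W.shape[1] == 1 else "dense"

    @property
    def embed_dim(self) -> int:
        if self.fc1_mode == "timestep":
            return self.fc1_W.shape[0]
        return self.fc1_W.shape[0] // self.fc1_W.shape[1]

    @property
    def n_features(self) -> int | None:
        """Expected input length p (dense mode only)."""
        return None if self.fc1_mode == "timestep" else self.fc1_W.shape[1]

    @property
    def n_classes(self) -> int:
        return self.fc2_W.shape[0]

    def to_dict(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every trainable parameter."""
        d = {"fc1_W": self.fc1_W, "fc1_b": self.fc1_b,
             "fc2_W": self.fc2_W, "fc2_b": self.fc2_b}
        for tag, layer in (("lstm1", self.lstm1), ("lstm2", self.lstm2)):
            for gate in ("f", "i", "C", "o"):
                d[f"{tag}_W_{gate}"] = getattr(layer, f"W_{gate}")
                d[f"{tag}_b_{gate}"] = getattr(layer, f"b_{gate}")
        return d

    def copy(self) -> "ScdlcParams":
        return from_dict({k: v.copy() for k, v in self.to_dict().items()})


def from_dict(d: dict[str, np.ndarray]) -> ScdlcParams:
    def layer(tag: str) -> LstmLayerParams:
        return LstmLayerParams(
            W_f=d[f"{tag}_W_f"], W_i=d[f"{tag}_W_i"],
            W_C=d[f"{tag}_W_C"], W_o=d[f"{tag}_W_o"],
            b_f=d[f"{tag}_b_f"], b_i=d[f"{tag}_b_i"],
            b_C=d[f"{tag}_b_C"], b_o=d[f"{tag}_b_o"],
        )
    return ScdlcParams(
        fc1_W=d["fc1_W"], fc1_b=d["fc1_b"],
        lstm1=layer("lstm1"), lstm2=layer("lstm2"),
        fc2_W=d["fc2_W"], fc2_b=d["fc2_b"],
    )


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    n_classes: int,
    hidden_size: int = 64,
    embed_dim: int | None = None,
    seed: int = 0,
    fc1_mode: str = "timestep",
    n_features: int | None = None,
) -> ScdlcParams:
    """Seeded Glorot-uniform initialization.

    Biases start at zero except the forget-gate biases, which start at 1.0
    so early training does not erase the cell state. ``fc1_mode='dense'``
    requires ``n_features`` (the sequence length p) to shape the first
    fully connected layer.
    """
    if embed_dim is None:
        embed_dim = hidden_size
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(101,)))

    def lstm(input_size: int) -> LstmLayerParams:
        h = hidden_size
        mats = {g: _glorot(rng, (h, h + input_size)) for g in ("f", "i", "C", "o")}
        return LstmLayerParams(
            W_f=mats["f"], W_i=mats["i"], W_C=mats["C"], W_o=mats["o"],
            b_f=np.ones(h), b_i=np.zeros(h), b_C=np.zeros(h), b_o=np.zeros(h),
        )

    if fc1_mode == "timestep":
        fc1_W = _glorot(rng, (embed_dim, 1))
    elif fc1_mode == "dense":
        if n_features is None:
            raise ValueError("fc1_mode='dense' requires n_features")
        fc1_W = _glorot(rng, (n_features * embed_dim, n_features))
    else:
        raise ValueError(f"unknown fc1_mode {fc1_mode!r}; expected 'timestep' or 'dense'")

    return ScdlcParams(
        fc1_W=fc1_W,
        fc1_b=np.zeros(fc1_W.shape[0]),
        lstm1=lstm(embed_dim),
        lstm2=lstm(hidden_size),
        fc2_W=_glorot(rng, (n_classes, hidden_size)),
        fc2_b=np.zeros(n_classes),
    )


def fc_relu(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fully connected layer with ReLU activation: a = max(0, Wx + b)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or W.ndim != 2 or W.shape[1] != x.shape[0]:
        raise ValueError(f"shape mismatch: W {W.shape}, x {x.shape}")
    if b.shape != (W.shape[0],):
        raise ValueError(f"bias length {b.shape} != {W.shape[0]}")
    return np.maximum(0.0, W @ x + b)


def lstm_step(x_t: np.ndarray, state: LstmState, params: LstmLayerParams) -> LstmState:
    """One LSTM timestep.

    f = sigma(W_f [h, x] + b_f); i = sigma(W_i [h, x] + b_i);
    Ctilde = tanh(W_C [h, x] + b_C); C' = f*C + i*Ctilde;
    o = sigma(W_o [h, x] + b_o); h' = o * tanh(C').
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    if x_t.shape != (params.input_size,):
        raise ValueError(f"input length {x_t.shape} != {params.input_size}")
    if state.h.shape != (params.hidden_size,):
        raise ValueError(f"state length {state.h.shape} != {params.hidden_size}")
    z = np.concatenate([state.h, x_t])
    f = _sigmoid(params.W_f @ z + params.b_f)
    i = _sigmoid(params.W_i @ z + params.b_i)
    c_tilde = np.tanh(params.W_C @ z + params.b_C)
    c_new = f * state.C + i * c_tilde
    o = _sigmoid(params.W_o @ z + params.b_o)
    h_new = o * np.tanh(c_new)
    return LstmState(h=h_new, C=c_new)


def softmax(y: np.ndarray) -> np.ndarray:
    """Numerically stable softmax along the last axis."""
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("softmax of empty input")
    shifted = y - y.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def predict(probabilities: np.ndarray) -> int | np.ndarray:
    """Argmax class; ties broken by lowest class index."""
    p = np.asarray(probabilities)
    if p.ndim == 1:
        return int(np.argmax(p))
    return np.argmax(p, axis=-1)


def _dropout_mask(rng: np.random.Generator, shape, keep_prob: float) -> np.ndarray:
    """Inverted-scaling dropout mask: kept units are scaled by 1/keep_prob."""
    return (rng.random(shape) < keep_prob) / keep_prob


def forward_batch(
    X: np.ndarray,
    params: ScdlcParams,
    keep_prob: float = 1.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Run the full network on a batch.

    ``X`` has shape (N, p): each row is one cell's expression over the p
    selected genes in descending-BW order; column t is timestep t.
    Dropout (inverted scaling) applies to each LSTM sublayer's *output*
    — never to its own recurrence — only when ``training`` is true.
    Returns (N, M) class probabilities, plus the backprop cache if
    requested.

    The per-timestep input projections (the fc1 embeddings and their
    contribution to sublayer 1's gate preactivations) are batched over
    all timesteps in single matrix products; the recurrent parts run in
    the timestep loop. The result is identical to composing ``fc_relu``
    and ``lstm_step`` stepwise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, p = X.shape
    if p == 0:
        raise ValueError("empty expression sequence")
    H = params.hidden_size
    D = params.embed_dim
    use_dropout = training and keep_prob < 1.0
    if use_dropout and rng is None:
        raise ValueError("training-mode dropout requires an rng")

    Ws1, bs1 = params.lstm1.stacked()
    Ws2, bs2 = params.lstm2.stacked()
    W1h, W1x = Ws1[:, :H], Ws1[:, H:]  # recurrent / input halves
    W2h, W2x = Ws2[:, :H], Ws2[:, H:]

    # fc1 embeddings for every timestep at once: (p, N, D)
    if params.fc1_mode == "timestep":
        A = np.maximum(0.0, X.T[:, :, None] * params.fc1_W[:, 0][None, None, :]
                       + params.fc1_b[None, None, :])
    else:
        if params.n_features != p:
            raise ValueError(
                f"expression length {p} != fc1 input width {params.n_features}"
            )
        A = np.maximum(0.0, X @ params.fc1_W.T + params.fc1_b)
        A = np.ascontiguousarray(A.reshape(n, p, D).transpose(1, 0, 2))
    # input contribution to sublayer 1 preactivations, all timesteps
    P1 = (A.reshape(p * n, D) @ W1x.T).reshape(p, n, 4 * H) + bs1

    h1 = np.zeros((n, H)); C1 = np.zeros((n, H))
    h2 = np.zeros((n, H)); C2 = np.zeros((n, H))

    if return_cache:
        G1 = np.empty((p, n, 4 * H)); G2 = np.empty((p, n, 4 * H))
        C1s = np.empty((p, n, H)); C2s = np.empty((p, n, H))
        T1s = np.empty((p, n, H)); T2s = np.empty((p, n, H))
        H1s = np.empty((p, n, H)); H2s = np.empty((p, n, H))
        H1out = np.empty((p, n, H))
        M1 = np.empty((p, n, H)) if use_dropout else None

    m1 = None
    for t in range(p):
        # sublayer 1: gates in stacked order [f, i, C, o]
        pre1 = h1 @ W1h.T + P1[t]
        g1 = _sigmoid(pre1)
        ct1 = np.tanh(pre1[:, 2 * H:3 * H])
        f1, i1, o1 = g1[:, :H], g1[:, H:2 * H], g1[:, 3 * H:]
        C1 = f1 * C1 + i1 * ct1
        tanhC1 = np.tanh(C1)
        h1 = o1 * tanhC1
        if use_dropout:
            m1 = _dropout_mask(rng, (n, H), keep_prob)
            h1_out = h1 * m1
        else:
            h1_out = h1

        # sublayer 2, fed by the (dropped) output of sublayer 1
        pre2 = h2 @ W2h.T + h1_out @ W2x.T + bs2
        g2 = _sigmoid(pre2)
        ct2 = np.tanh(pre2[:, 2 * H:3 * H])
        f2, i2, o2 = g2[:, :H], g2[:, H:2 * H], g2[:, 3 * H:]
        C2 = f2 * C2 + i2 * ct2
        tanhC2 = np.tanh(C2)
        h2 = o2 * tanhC2

        if return_cache:
            g1c = g1.copy(); g1c[:, 2 * H:3 * H] = ct1
            g2c = g2.copy(); g2c[:, 2 * H:3 * H] = ct2
            G1[t] = g1c; G2[t] = g2c
            C1s[t] = C1; C2s[t] = C2
            T1s[t] = tanhC1; T2s[t] = tanhC2
            H1s[t] = h1; H2s[t] = h2; H1out[t] = h1_out
            if use_dropout:
                M1[t] = m1

    m2 = _dropout_mask(rng, (n, H), keep_prob) if use_dropout else None
    h2_out = h2 * m2 if use_dropout else h2
    logits = h2_out @ params.fc2_W.T + params.fc2_b
    probs = softmax(logits)
    if not return_cache:
        return probs
    cache = {
        "X": X, "A": A, "G1": G1, "G2": G2, "C1": C1s, "C2": C2s,
        "T1": T1s, "T2": T2s, "H1": H1s, "H2": H2s, "H1out": H1out,
        "mask1": M1, "mask2": m2, "h2_out": h2_out, "probs": probs,
    }
    return probs, cache


def forward(
    expression: np.ndarray,
    params: ScdlcParams,
    keep_prob: float = 1.0,
    training: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Class-probability vector for one cell's ordered expression vector."""
    expression = np.asarray(expression, dtype=np.float64)
    if expression.ndim != 1:
        raise ValueError("expression must be a 1-D vector; use forward_batch for batches")
    rng = None
    if training and keep_prob < 1.0:
        if seed is None:
            raise ValueError("training-mode dropout requires a seed")
        rng = np.random.default_rng(seed)
    return forward_batch(expression[None, :], params, keep_prob, training, rng)[0]


def save_params(path, params: ScdlcParams, config: dict | None = None) -> None:
    """Serialize all parameter arrays plus a config echo to one .npz file."""
    import json

    arrays = params.to_dict()
    meta = json.dumps({"format_version": CHECKPOINT_FORMAT_VERSION,
                       "config": config or {}})
    np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_params(path) -> tuple[ScdlcParams, dict]:
    """Load a checkpoint; round-trips bit-exactly."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format: {meta.get('format_version')}")
        arrays = {k: data[k] for k in data.files if k != "_meta"}
    return from_dict(arrays), meta.get("config", {})


def prepare_inputs(matrix: CountMatrix, selected: np.ndarray, raw: bool = False) -> np.ndarray:
    """(N, p) network input: preprocess and slice the selected genes in order."""
    values = matrix.counts.astype(np.float64) if raw else log_normalize(matrix.counts)
    return values[np.asarray(selected, dtype=np.int64), :].T
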