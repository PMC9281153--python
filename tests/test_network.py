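"""Forward-model components: FC-ReLU, LSTM step, softmax, full forward."""

import math

import numpy as np
import pytest

from scdlc.network import (
    LstmLayerParams,
    LstmState,
    ScdlcParams,
    fc_relu,
    forward,
    forward_batch,
    init_params,
    load_params,
    log_normalize,
    lstm_step,
    predict,
    save_params,
    softmax,
)


def sigmoid_scalar(z):
    return 1.0 / (1.0 + math.exp(-z))


def lstm_step_oracle(x, h_prev, c_prev, params):
    """Element-by-element transcription of the gate recurrence."""
    hidden = len(h_prev)
    z = list(h_prev) + list(x)

    def affine(W, b, row):
        return sum(W[row][j] * z[j] for j in range(len(z))) + b[row]

    h_new, c_new = [], []
    for u in range(hidden):
        f = sigmoid_scalar(affine(params.W_f, params.b_f, u))
        i = sigmoid_scalar(affine(params.W_i, params.b_i, u))
        c_t = math.tanh(affine(params.W_C, params.b_C, u))
        c = f * c_prev[u] + i * c_t
        o = sigmoid_scalar(affine(params.W_o, params.b_o, u))
        c_new.append(c)
        h_new.append(o * math.tanh(c))
    return h_new, c_new


def random_lstm_params(rng, hidden, input_size):
    shape = (hidden, hidden + input_size)
    return LstmLayerParams(
        W_f=rng.normal(size=shape), W_i=rng.normal(size=shape),
        W_C=rng.normal(size=shape), W_o=rng.normal(size=shape),
        b_f=rng.normal(size=hidden), b_i=rng.normal(size=hidden),
        b_C=rng.normal(size=hidden), b_o=rng.normal(size=hidden),
    )


class TestFcRelu:
    def test_negative_entries_clamp_to_zero(self):
        out = fc_relu(np.array([1.0]), np.zeros((2, 1)), np.array([-1.0, 2.0]))
        np.testing.assert_array_equal(out, [0.0, 2.0])

    def test_identity_on_nonnegative_orthant(self):
        x = np.array([0.0, 1.5, 3.0])
        np.testing.assert_array_equal(fc_relu(x, np.eye(3), np.zeros(3)), x)

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            W = rng.normal(size=(4, 3)); b = rng.normal(size=4)
            x = rng.normal(size=3)
            expected = [max(0.0, sum(W[r][c] * x[c] for c in range(3)) + b[r])
                        for r in range(4)]
            np.testing.assert_allclose(fc_relu(x, W, b), expected, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fc_relu(np.ones(3), np.ones((2, 4)), np.ones(2))


class TestLstmStep:
    def test_all_zero_weights_zero_state(self):
        params = LstmLayerParams(*(np.zeros((2, 3)),) * 4, *(np.zeros(2),) * 4)
        state = lstm_step(np.zeros(1), LstmState(np.zeros(2), np.zeros(2)), params)
        np.testing.assert_array_equal(state.h, 0.0)
        np.testing.assert_array_equal(state.C, 0.0)

    def test_zero_weights_nonzero_cell_state(self):
        # gates are all sigma(0)=0.5, candidate is tanh(0)=0:
        # C' = 0.5 c, h' = 0.5 tanh(0.5 c)
        params = LstmLayerParams(*(np.zeros((2, 3)),) * 4, *(np.zeros(2),) * 4)
        c = np.array([0.8, -1.2])
        state = lstm_step(np.zeros(1), LstmState(np.zeros(2), c), params)
        np.testing.assert_allclose(state.C, 0.5 * c, rtol=1e-12)
        np.testing.assert_allclose(state.h, 0.5 * np.tanh(0.5 * c), rtol=1e-12)

    def test_four_step_sequence_matches_oracle(self):
        rng = np.random.default_rng(9)
        params = random_lstm_params(rng, hidden=3, input_size=2)
        state = LstmState(np.zeros(3), np.zeros(3))
        h_ref, c_ref = [0.0] * 3, [0.0] * 3
        for _ in range(4):
            x = rng.normal(size=2)
            state = lstm_step(x, state, params)
            h_ref, c_ref = lstm_step_oracle(x, h_ref, c_ref, params)
        np.testing.assert_allclose(state.h, h_ref, rtol=1e-10)
        np.testing.assert_allclose(state.C, c_ref, rtol=1e-10)

    def test_gate_ranges(self):
        rng = np.random.default_rng(2)
        params = random_lstm_params(rng, hidden=4, input_size=4)
        state = LstmState(np.zeros(4), np.zeros(4))
        for _ in range(10):
            state = lstm_step(rng.normal(size=4) * 5, state, params)
            assert np.all(np.abs(state.h) < 1.0)

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        params = random_lstm_params(rng, hidden=3, input_size=2)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(5), LstmState(np.zeros(3), np.zeros(3)), params)


class TestSoftmax:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax(np.zeros(2)), [0.5, 0.5])

    def test_shift_invariance(self):
        y = np.array([0.3, -1.2, 2.0])
        np.testing.assert_allclose(softmax(y), softmax(y + 100.0), rtol=1e-12)

    def test_direct_evaluation(self):
        out = softmax(np.array([1.0, 2.0, 3.0]))
        e = np.exp([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, e / e.sum(), rtol=1e-12)
        np.testing.assert_allclose(out, [0.0900, 0.2447, 0.6652], atol=5e-5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.array([]))


class TestForward:
    def test_zero_readout_gives_uniform(self):
        params = init_params(n_classes=4, hidden_size=3, seed=0)
        params.fc2_W[:] = 0.0
        params.fc2_b[:] = 0.0
        probs = forward(np.array([1.0, 2.0, 3.0]), params)
        np.testing.assert_allclose(probs, 0.25, rtol=1e-12)

    def test_output_is_probability_vector(self):
        rng = np.random.default_rng(5)
        params = init_params(n_classes=3, hidden_size=4, seed=1)
        for _ in range(10):
            probs = forward(rng.normal(size=6), params)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((probs > 0) & (probs < 1))

    def test_matches_hand_unrolled_composition(self):
        """The batched forward equals composing the scalar-step oracles."""
        rng = np.random.default_rng(17)
        for trial in range(25):
            params = init_params(n_classes=2, hidden_size=2, embed_dim=2,
                                 seed=100 + trial)
            x = rng.normal(size=3)
            h1, c1 = [0.0, 0.0], [0.0, 0.0]
            h2, c2 = [0.0, 0.0], [0.0, 0.0]
            for t in range(3):
                a = [max(0.0, params.fc1_W[d, 0] * x[t] + params.fc1_b[d])
                     for d in range(2)]
                h1, c1 = lstm_step_oracle(a, h1, c1, params.lstm1)
                h2, c2 = lstm_step_oracle(h1, h2, c2, params.lstm2)
            logits = [sum(params.fc2_W[m, u] * h2[u] for u in range(2))
                      + params.fc2_b[m] for m in range(2)]
            e = [math.exp(v - max(logits)) for v in logits]
            expected = [v / sum(e) for v in e]
            np.testing.assert_allclose(forward(x, params), expected, rtol=1e-9)

    def test_eval_mode_is_deterministic(self):
        params = init_params(n_classes=2, hidden_size=4, seed=3)
        x = np.linspace(0, 1, 5)
        p1 = forward(x, params)
        p2 = forward(x, params)
        np.testing.assert_array_equal(p1, p2)

    def test_training_dropout_is_stochastic_but_seeded(self):
        params = init_params(n_classes=2, hidden_size=4, seed=3)
        x = np.linspace(0, 1, 5)
        a = forward(x, params, keep_prob=0.5, training=True, seed=1)
        b = forward(x, params, keep_prob=0.5, training=True, seed=1)
        c = forward(x, params, keep_prob=0.5, training=True, seed=2)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)

    def test_batch_rows_match_single_calls(self):
        rng = np.random.default_rng(8)
        params = init_params(n_classes=3, hidden_size=5, seed=2)
        X = rng.normal(size=(7, 4))
        batch = forward_batch(X, params)
        singles = np.array([forward(x, params) for x in X])
        np.testing.assert_allclose(batch, singles, rtol=1e-12)


class TestPredict:
    @pytest.mark.parametrize("probs,expected", [
        ([0.1, 0.7, 0.2], 1),
        ([0.5, 0.5], 0),
        ([1 / 3, 1 / 3, 1 / 3], 0),
    ])
    def test_argmax_with_low_index_ties(self, probs, expected):
        assert predict(np.array(probs)) == expected


class TestCheckpoint:
    def test_round_trip_is_bit_exact(self, tmp_path):
        params = init_params(n_classes=3, hidden_size=6, seed=11)
        path = tmp_path / "model.npz"
        save_params(path, params, config={"note": "test"})
        loaded, config = load_params(path)
        assert config == {"note": "test"}
        for k, v in params.to_dict().items():
            np.testing.assert_array_equal(v, loaded.to_dict()[k])


class TestLogNormalize:
    def test_equalizes_depths_then_logs(self):
        counts = np.array([[10, 100], [10, 100]])
        out = log_normalize(counts)
        # both cells scaled to the median depth; values equal after scaling
        np.testing.assert_allclose(out[:, 0], out[:, 1], rtol=1e-12)

    def test_zero_depth_cell_is_safe(self):
        counts = np.array([[0, 4], [0, 4]])
        out = log_normalize(counts)
        assert np.all(np.isfinite(out))
        np.testing.assert_array_equal(out[:, 0], 0.0)
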