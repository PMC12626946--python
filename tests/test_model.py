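"""Forward-pass semantics of the BiLSTM-CNN: initialization determinism,
convolution against a brute-force oracle, directional symmetry, dropout
placement and checkpointing."""

import numpy as np
import pytest

from paratopenet.data import LabeledChain, pad_and_mask
from paratopenet.encoding import encode, encode_one_hot
from paratopenet.model import (
    ModelConfig,
    bilstm_contextualize,
    conv1d_same,
    init_model,
    load_checkpoint,
    predict_residues,
    save_checkpoint,
)
from paratopenet import nn


def conv_oracle(X, W, b, relu=False):
    """Independent nested-loop 'same' convolution (zero padding, pad-left
    floor((k-1)/2))."""
    B, L, C_in = X.shape
    k, _, C_out = W.shape
    left = (k - 1) // 2
    Z = np.zeros((B, L, C_out))
    for bi in range(B):
        for t in range(L):
            for co in range(C_out):
                acc = b[co]
                for i in range(k):
                    src = t - left + i
                    if 0 <= src < L:
                        for ci in range(C_in):
                            acc += X[bi, src, ci] * W[i, ci, co]
                Z[bi, t, co] = acc
    if relu:
        Z = np.maximum(Z, 0.0)
    return Z


class TestConv1dSame:
    def test_sliding_sum_example(self):
        X = np.array([[[1.0], [2.0], [3.0], [4.0]]])
        Z = conv1d_same(X, np.ones((3, 1, 1)), np.zeros(1), activation="none")
        assert Z[0, :, 0].tolist() == [3.0, 6.0, 9.0, 7.0]

    def test_kernel_size_one_identity(self):
        X = np.random.default_rng(0).normal(size=(2, 5, 1))
        Z = conv1d_same(X, np.ones((1, 1, 1)), np.zeros(1), activation="none")
        assert np.allclose(Z, X)

    def test_relu_nonnegative(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 6, 3))
        Z = conv1d_same(X, rng.normal(size=(5, 3, 2)), rng.normal(size=2))
        assert (Z >= 0).all()

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            B = rng.integers(1, 3)
            L = rng.integers(2, 9)
            C_in = rng.integers(1, 4)
            C_out = rng.integers(1, 4)
            k = int(rng.integers(1, L + 1))
            X = rng.normal(size=(B, L, C_in))
            W = rng.normal(size=(k, C_in, C_out))
            b = rng.normal(size=C_out)
            ours = conv1d_same(X, W, b, activation="none")
            assert np.allclose(ours, conv_oracle(X, W, b), atol=1e-6)

    def test_kernel_larger_than_sequence_errors(self):
        X = np.zeros((1, 4, 1))
        with pytest.raises(ValueError, match="exceeds"):
            conv1d_same(X, np.ones((5, 1, 1)), np.zeros(1))


class TestInitModel:
    def test_same_seed_bit_identical(self):
        a = init_model(ModelConfig(seed=9))
        b = init_model(ModelConfig(seed=9))
        assert a.params.keys() == b.params.keys()
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_different_seed_differs(self):
        a = init_model(ModelConfig(seed=9))
        b = init_model(ModelConfig(seed=10))
        assert any(not np.array_equal(a.params[k], b.params[k]) for k in a.params)

    @pytest.mark.parametrize("encoding", ["onehot", "embedding"])
    def test_default_parameter_count_under_10m(self, encoding):
        state = init_model(ModelConfig(encoding=encoding, kernel_sizes=(130,)))
        assert state.n_parameters() < 10_000_000

    @pytest.mark.parametrize("bad", [
        dict(kernel_sizes=(0,)),
        dict(kernel_sizes=(131,)),
        dict(hidden_size=0),
        dict(dropout_p=1.0),
        dict(encoding="words"),
    ])
    def test_invalid_config_errors(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)


class TestBiLSTM:
    def test_output_dimension_is_2h(self, tiny_batch):
        state = init_model(ModelConfig(hidden_size=64, kernel_sizes=(3,),
                                       padded_length=6, seed=0))
        h = bilstm_contextualize(state, tiny_batch)
        assert h.shape == (2, 6, 128)

    def test_eval_mode_deterministic(self, tiny_config, tiny_batch):
        state = init_model(tiny_config)
        a = bilstm_contextualize(state, tiny_batch)
        b = bilstm_contextualize(state, tiny_batch)
        assert np.array_equal(a, b)

    def test_reversal_swaps_directions(self):
        # on a full-length (unpadded) input, reversing the sequence and
        # swapping the two directional parameter sets must produce the
        # position-reversed output with its two halves swapped
        L, H = 5, 3
        seq = "ACDWY"
        cfg = ModelConfig(hidden_size=H, kernel_sizes=(3,), padded_length=L, seed=5)
        state = init_model(cfg)
        swapped = init_model(cfg)
        for name in list(swapped.params):
            if name.startswith("lstm_fwd"):
                other = name.replace("fwd", "bwd")
                swapped.params[name] = state.params[other].copy()
                swapped.params[other] = state.params[name].copy()

        batch = encode_one_hot([pad_and_mask(LabeledChain("c", "H", seq, (0,) * L), L)])
        rev_batch = encode_one_hot(
            [pad_and_mask(LabeledChain("c", "H", seq[::-1], (0,) * L), L)]
        )
        h = bilstm_contextualize(state, batch)
        h_rev = bilstm_contextualize(swapped, rev_batch)
        expected = np.concatenate(
            [h[:, ::-1, H:], h[:, ::-1, :H]], axis=2
        )
        assert np.allclose(h_rev, expected, atol=1e-10)


class TestPredictResidues:
    def test_probability_shape_and_range(self, tiny_config, tiny_batch):
        state = init_model(tiny_config)
        out = predict_residues(state, tiny_batch)
        assert out.probabilities.shape == (2, 6)
        assert ((out.probabilities > 0) & (out.probabilities < 1)).all()

    def test_eval_bit_stable(self, tiny_config, tiny_batch):
        state = init_model(tiny_config)
        a = predict_residues(state, tiny_batch)
        b = predict_residues(state, tiny_batch)
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_zero_dropout_training_equals_eval(self, tiny_config, tiny_batch):
        state = init_model(tiny_config)  # dropout_p = 0
        rng = np.random.default_rng(0)
        tr = predict_residues(state, tiny_batch, training=True, rng=rng)
        ev = predict_residues(state, tiny_batch)
        assert np.allclose(tr.probabilities, ev.probabilities)

    def test_dropout_changes_training_output(self, tiny_batch):
        cfg = ModelConfig(
            encoding="onehot", hidden_size=2, kernel_sizes=(3,), conv_channels=2,
            dropout_p=0.5, padded_length=6, seed=3,
        )
        state = init_model(cfg)
        rng = np.random.default_rng(0)
        tr = predict_residues(state, tiny_batch, training=True, rng=rng)
        ev = predict_residues(state, tiny_batch)
        assert not np.allclose(tr.probabilities, ev.probabilities)

    def test_probabilities_monotone_in_logits(self, tiny_config, tiny_batch):
        state = init_model(tiny_config)
        out = predict_residues(state, tiny_batch)
        order_l = np.argsort(out.logits.ravel())
        order_p = np.argsort(out.probabilities.ravel())
        assert np.array_equal(order_l, order_p)

    def test_batch_permutation_equivariance(self, small_dataset):
        chains = small_dataset.chains()[:6]
        cfg = ModelConfig(hidden_size=4, kernel_sizes=(7,), conv_channels=4, seed=2)
        state = init_model(cfg)
        batch = encode([pad_and_mask(c, 130) for c in chains], "onehot")
        out = predict_residues(state, batch)
        perm = [3, 0, 5, 1, 4, 2]
        batch_p = encode([pad_and_mask(chains[i], 130) for i in perm], "onehot")
        out_p = predict_residues(state, batch_p)
        assert np.allclose(out_p.probabilities, out.probabilities[perm])

    def test_multi_kernel_concatenation_degenerate(self, tiny_batch):
        # a single-kernel model and a "multi-kernel" model with a one-element
        # kernel list are the same configuration and must agree exactly
        a = init_model(ModelConfig(hidden_size=2, kernel_sizes=(3,),
                                   conv_channels=2, padded_length=6, seed=3))
        b = init_model(ModelConfig(hidden_size=2, kernel_sizes=tuple([3]),
                                   conv_channels=2, padded_length=6, seed=3))
        pa = predict_residues(a, tiny_batch).probabilities
        pb = predict_residues(b, tiny_batch).probabilities
        assert np.array_equal(pa, pb)

    def test_multi_kernel_runs(self, tiny_batch):
        cfg = ModelConfig(hidden_size=2, kernel_sizes=(3, 5), conv_channels=2,
                          padded_length=6, seed=3)
        state = init_model(cfg)
        out = predict_residues(state, tiny_batch)
        assert out.conv_features.shape == (2, 6, 4)


def test_checkpoint_roundtrip(tmp_path, tiny_config, tiny_batch):
    state = init_model(tiny_config)
    before = predict_residues(state, tiny_batch).probabilities
    path = tmp_path / "model.npz"
    save_checkpoint(state, path)
    loaded = load_checkpoint(path)
    assert loaded.config == tiny_config
    after = predict_residues(loaded, tiny_batch).probabilities
    assert np.array_equal(before, after)


def test_lstm_gradcheck_small():
    # finite-difference check of the raw LSTM layer in isolation
    rng = np.random.default_rng(0)
    B, L, D, H = 2, 4, 3, 2
    X = rng.normal(size=(B, L, D))
    Wx = rng.normal(size=(D, 4 * H)) * 0.4
    Wh = rng.normal(size=(H, 4 * H)) * 0.4
    b = rng.normal(size=4 * H) * 0.4
    proj = rng.normal(size=H)

    def loss(Wx_, Wh_, b_):
        Hs, _ = nn.lstm_forward(X, Wx_, Wh_, b_)
        return float((Hs @ proj).sum())

    Hs, cache = nn.lstm_forward(X, Wx, Wh, b)
    dH = np.broadcast_to(proj, Hs.shape).copy()
    dX, dWx, dWh, db = nn.lstm_backward(dH, cache, Wx, Wh)
    eps = 1e-6
    for arr, grad in ((Wx, dWx), (Wh, dWh), (b, db)):
        it = np.nditer(arr, flags=["multi_index"])
        for _ in range(min(arr.size, 20)):
            ix = it.multi_index
            old = arr[ix]
            arr[ix] = old + eps
            lp = loss(Wx, Wh, b)
            arr[ix] = old - eps
            lm = loss(Wx, Wh, b)
            arr[ix] = old
            assert abs((lp - lm) / (2 * eps) - grad[ix]) < 1e-5
            it.iternext()
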