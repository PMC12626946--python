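"""Low-level neural-network primitives with hand-derived gradients.

Everything here operates on plain NumPy arrays in float64 and exposes an
explicit forward/backward pair, so the whole model is differentiable without
an autograd framework and gradients can be verified against finite
differences.  Conventions:

* sequences are (batch, length, features) arrays;
* the LSTM gate pre-activation is laid out as ``[i | f | g | o]`` blocks of
  width H (input, forget, cell-candidate, output gates);
* "same" convolution pads ``floor((k-1)/2)`` zeros on the left and
  ``ceil((k-1)/2)`` on the right, so output length equals input length for
  every kernel size including even ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable piecewise form
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Dropout (inverted scaling: expectation-preserving at train time)
# ---------------------------------------------------------------------------

def dropout_forward(
    x: np.ndarray, p: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (output, keep_mask/(1-p)); multiply gradients by the same mask."""
    if p <= 0.0:
        return x, np.ones_like(x)
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * keep, keep


# ---------------------------------------------------------------------------
# LSTM (single layer, batch-first)
# ---------------------------------------------------------------------------

@dataclass
class LSTMCache:
    X: np.ndarray          # (B, L, D) inputs
    gates: np.ndarray      # (L, B, 4H) post-activation gates [i|f|g|o]
    c: np.ndarray          # (L, B, H) cell states
    h: np.ndarray          # (L, B, H) hidden states
    tanh_c: np.ndarray     # (L, B, H)


def lstm_forward(
    X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, LSTMCache]:
    """Run a unidirectional LSTM over X (B, L, D); returns (H_seq, cache).

    Initial hidden and cell states are zero.  The input projection for all
    time steps is computed as one matmul; the recurrence loops over time.
    """
    B, L, D = X.shape
    H = Wh.shape[0]
    Ain = X.reshape(B * L, D) @ Wx
    Ain = Ain.reshape(B, L, 4 * H) + b

    gates = np.empty((L, B, 4 * H))
    cs = np.empty((L, B, H))
    hs = np.empty((L, B, H))
    tanh_cs = np.empty((L, B, H))
    h_prev = np.zeros((B, H))
    c_prev = np.zeros((B, H))
    for t in range(L):
        A = Ain[:, t, :] + h_prev @ Wh
        i = sigmoid(A[:, 0 * H:1 * H])
        f = sigmoid(A[:, 1 * H:2 * H])
        g = np.tanh(A[:, 2 * H:3 * H])
        o = sigmoid(A[:, 3 * H:4 * H])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[t, :, 0 * H:1 * H] = i
        gates[t, :, 1 * H:2 * H] = f
        gates[t, :, 2 * H:3 * H] = g
        gates[t, :, 3 * H:4 * H] = o
        cs[t] = c
        hs[t] = h
        tanh_cs[t] = tc
        h_prev, c_prev = h, c
    H_seq = hs.transpose(1, 0, 2)  # (B, L, H)
    return H_seq, LSTMCache(X, gates, cs, hs, tanh_cs)


def lstm_backward(
    dH_seq: np.ndarray, cache: LSTMCache, Wx: np.ndarray, Wh: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Backprop-through-time. Returns (dX, dWx, dWh, db)."""
    B, L, D = cache.X.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dA_all = np.empty((L, B, 4 * H))

    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    dH = dH_seq.transpose(1, 0, 2)  # (L, B, H)
    for t in range(L - 1, -1, -1):
        i = cache.gates[t, :, 0 * H:1 * H]
        f = cache.gates[t, :, 1 * H:2 * H]
        g = cache.gates[t, :, 2 * H:3 * H]
        o = cache.gates[t, :, 3 * H:4 * H]
        tc = cache.tanh_c[t]
        c_prev = cache.c[t - 1] if t > 0 else np.zeros((B, H))

        dh = dH[t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f

        dA = np.empty((B, 4 * H))
        dA[:, 0 * H:1 * H] = di * i * (1.0 - i)
        dA[:, 1 * H:2 * H] = df * f * (1.0 - f)
        dA[:, 2 * H:3 * H] = dg * (1.0 - g * g)
        dA[:, 3 * H:4 * H] = do * o * (1.0 - o)
        dA_all[t] = dA

        h_prev = cache.h[t - 1] if t > 0 else np.zeros((B, H))
        dWh += h_prev.T @ dA
        dh_next = dA @ Wh.T

    # input-side gradients batched over all time steps
    dA_flat = dA_all.transpose(1, 0, 2).reshape(B * L, 4 * H)
    X_flat = cache.X.reshape(B * L, D)
    dWx = X_flat.T @ dA_flat
    db = dA_flat.sum(axis=0)
    dX = (dA_flat @ Wx.T).reshape(B, L, D)
    return dX, dWx, dWh, db


def bilstm_forward(
    X: np.ndarray,
    params: dict[str, np.ndarray],
) -> tuple[np.ndarray, tuple[LSTMCache, LSTMCache]]:
    """Bidirectional LSTM: concatenated forward and reversed-input states.

    Output is (B, L, 2H): the first H features come from the forward pass,
    the last H from the backward pass re-aligned to original positions.
    """
    Hf, cache_f = lstm_forward(
        X, params["lstm_fwd_Wx"], params["lstm_fwd_Wh"], params["lstm_fwd_b"]
    )
    Hb_rev, cache_b = lstm_forward(
        X[:, ::-1, :], params["lstm_bwd_Wx"], params["lstm_bwd_Wh"], params["lstm_bwd_b"]
    )
    Hb = Hb_rev[:, ::-1, :]
    return np.concatenate([Hf, Hb], axis=2), (cache_f, cache_b)


def bilstm_backward(
    dH: np.ndarray,
    caches: tuple[LSTMCache, LSTMCache],
    params: dict[str, np.ndarray],
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Gradients of the bidirectional layer; returns (dX, param grads)."""
    H = params["lstm_fwd_Wh"].shape[0]
    cache_f, cache_b = caches
    dXf, dWxf, dWhf, dbf = lstm_backward(
        dH[:, :, :H], cache_f, params["lstm_fwd_Wx"], params["lstm_fwd_Wh"]
    )
    dXb_rev, dWxb, dWhb, dbb = lstm_backward(
        np.ascontiguousarray(dH[:, ::-1, H:]), cache_b,
        params["lstm_bwd_Wx"], params["lstm_bwd_Wh"],
    )
    dX = dXf + dXb_rev[:, ::-1, :]
    grads = {
        "lstm_fwd_Wx": dWxf, "lstm_fwd_Wh": dWhf, "lstm_fwd_b": dbf,
        "lstm_bwd_Wx": dWxb, "lstm_bwd_Wh": dWhb, "lstm_bwd_b": dbb,
    }
    return dX, grads


# ---------------------------------------------------------------------------
# 1-D "same" convolution along the sequence axis
# ---------------------------------------------------------------------------

def same_padding(k: int) -> tuple[int, int]:
    """(left, right) zero-padding that preserves sequence length."""
    return (k - 1) // 2, k - 1 - (k - 1) // 2


def conv1d_same_forward(
    X: np.ndarray, W: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Length-preserving 1-D convolution.

    X: (B, L, C_in); W: (k, C_in, C_out); b: (C_out,).
    Returns (Z of shape (B, L, C_out), padded input kept for backward).
    Implemented as k shifted matmuls, avoiding a large im2col buffer.
    """
    B, L, C_in = X.shape
    k = W.shape[0]
    if k > L:
        raise ValueError(f"kernel size {k} exceeds sequence length {L}")
    left, right = same_padding(k)
    Xp = np.zeros((B, L + left + right, C_in))
    Xp[:, left:left + L, :] = X
    Z = np.broadcast_to(b, (B, L, W.shape[2])).copy()
    for i in range(k):
        Z += Xp[:, i:i + L, :] @ W[i]
    return Z, Xp


def conv1d_same_backward(
    dZ: np.ndarray, Xp: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of conv1d_same_forward. Returns (dX, dW, db)."""
    B, L, C_out = dZ.shape
    k, C_in, _ = W.shape
    left, _ = same_padding(k)
    dW = np.zeros_like(W)
    dXp = np.zeros_like(Xp)
    dZ_flat = dZ.reshape(B * L, C_out)
    for i in range(k):
        win = Xp[:, i:i + L, :].reshape(B * L, C_in)
        dW[i] = win.T @ dZ_flat
        dXp[:, i:i + L, :] += dZ @ W[i].T
    db = dZ_flat.sum(axis=0)
    dX = dXp[:, left:left + Xp.shape[1] - (k - 1), :]
    return np.ascontiguousarray(dX), dW, db


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(
        self,
        param_names: list[str],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {n: None for n in param_names}
        self._v: dict[str, np.ndarray] = {n: None for n in param_names}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, g in grads.items():
            if self._m[name] is None:
                self._m[name] = np.zeros_like(g)
                self._v[name] = np.zeros_like(g)
            m = self._m[name]
            v = self._v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            params[name] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
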