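"""The BiLSTM-CNN paratope predictor as a seedable forward computation.

Pipeline per padded chain of length L::

    residues -> one-hot (21) or learnable embedding (21)
             -> dropout
             -> BiLSTM (hidden 64 per direction -> 128 per position)
             -> dropout
             -> 1-D same-padding convolution per kernel size, ReLU,
                feature maps concatenated channel-wise
             -> dropout
             -> per-position dense layer -> sigmoid -> binding probability

Dropout is active only in training mode; padded positions flow through the
network unhindered and are excluded later via the mask, never by truncation.
Pooling is deliberately absent so per-residue resolution is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .encoding import EncodedBatch, N_TOKENS, ONEHOT_ALPHABET, ONEHOT_DIM

KNOWN_KERNEL_SIZES = (7, 15, 31, 71, 130)
CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the BiLSTM-CNN predictor.

    ``hidden_size`` is the LSTM width per direction (contextual vectors are
    2x that).  ``kernel_sizes`` may hold several sizes whose feature maps are
    concatenated; a single mid-range kernel is the default.  ``kernel_size``
    equal to ``padded_length`` gives one receptive field spanning the whole
    padded sequence ("full-length" convolution).
    """

    encoding: str = "onehot"  # "onehot" | "embedding"
    hidden_size: int = 64
    kernel_sizes: tuple[int, ...] = (31,)
    conv_channels: int = 64
    dropout_p: float = 0.3
    dropout_embedding: bool = True
    padded_length: int = 130
    embed_dim: int = 21
    seed: int = 0

    def __post_init__(self):
        if self.encoding not in ("onehot", "embedding"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.conv_channels < 1:
            raise ValueError("conv_channels must be >= 1")
        if not self.kernel_sizes:
            raise ValueError("at least one kernel size required")
        for k in self.kernel_sizes:
            if not 1 <= k <= self.padded_length:
                raise ValueError(
                    f"kernel size {k} outside [1, {self.padded_length}]"
                )
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")

    @property
    def input_dim(self) -> int:
        return ONEHOT_DIM if self.encoding == "onehot" else self.embed_dim

    @property
    def total_conv_channels(self) -> int:
        return self.conv_channels * len(self.kernel_sizes)


@dataclass
class ModelState:
    """All learnable parameters, keyed by name, plus the config."""

    config: ModelConfig
    params: dict[str, np.ndarray]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "ModelState":
        return ModelState(self.config, {k: v.copy() for k, v in self.params.items()})


@dataclass
class ForwardOutput:
    """Per-position intermediates and predictions, all at padded length."""

    contextual: np.ndarray   # (B, L, 2H)
    conv_features: np.ndarray  # (B, L, C_total), post-ReLU
    logits: np.ndarray       # (B, L)
    probabilities: np.ndarray  # (B, L), sigmoid of logits


def init_model(config: ModelConfig) -> ModelState:
    """Deterministically initialize all parameters from ``config.seed``.

    LSTM/conv/dense weights are uniform on +-1/sqrt(fan_in) (the usual
    recurrent-net default); the embedding table is standard normal.
    """
    rng = np.random.default_rng(config.seed)
    H = config.hidden_size
    D = config.input_dim
    params: dict[str, np.ndarray] = {}

    if config.encoding == "embedding":
        params["embed"] = rng.standard_normal((N_TOKENS, config.embed_dim))

    s = 1.0 / np.sqrt(H)
    for direction in ("fwd", "bwd"):
        params[f"lstm_{direction}_Wx"] = rng.uniform(-s, s, (D, 4 * H))
        params[f"lstm_{direction}_Wh"] = rng.uniform(-s, s, (H, 4 * H))
        params[f"lstm_{direction}_b"] = rng.uniform(-s, s, 4 * H)

    for k in config.kernel_sizes:
        fan_in = k * 2 * H
        sk = 1.0 / np.sqrt(fan_in)
        params[f"conv{k}_W"] = rng.uniform(-sk, sk, (k, 2 * H, config.conv_channels))
        params[f"conv{k}_b"] = rng.uniform(-sk, sk, config.conv_channels)

    C = config.total_conv_channels
    sd = 1.0 / np.sqrt(C)
    params["dense_W"] = rng.uniform(-sd, sd, (C, 1))
    params["dense_b"] = rng.uniform(-sd, sd, 1)
    return ModelState(config, params)


def conv1d_same(
    features: np.ndarray,
    kernel: np.ndarray,
    bias: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """Length-preserving 1-D convolution over (B, L, C_in) features.

    ``kernel`` is (k, C_in, C_out).  Same padding puts floor((k-1)/2) zeros
    on the left and the remainder on the right, so odd kernels are symmetric.
    """
    if activation not in ("relu", "none"):
        raise ValueError(f"unknown activation {activation!r}")
    Z, _ = nn.conv1d_same_forward(features, kernel, bias)
    if activation == "relu":
        Z = np.maximum(Z, 0.0)
    return Z


def _input_features(
    state: ModelState, batch: EncodedBatch
) -> np.ndarray:
    cfg = state.config
    if cfg.encoding != batch.encoding:
        raise ValueError(
            f"batch encoding {batch.encoding!r} does not match model "
            f"config {cfg.encoding!r}"
        )
    if batch.padded_length != cfg.padded_length:
        raise ValueError(
            f"batch padded length {batch.padded_length} != model "
            f"padded length {cfg.padded_length}"
        )
    if cfg.encoding == "onehot":
        return batch.one_hot.astype(float)
    return state.params["embed"][batch.indices]


def _forward_full(
    state: ModelState,
    batch: EncodedBatch,
    training: bool,
    rng: np.random.Generator | None,
):
    """Forward pass retaining every intermediate needed for backprop."""
    cfg = state.config
    p = cfg.dropout_p if training else 0.0
    if training and p > 0.0 and rng is None:
        raise ValueError("training-mode dropout requires an rng")

    cache: dict = {}
    X = _input_features(state, batch)
    cache["X_raw"] = X
    if p > 0.0 and cfg.dropout_embedding:
        X, cache["drop_X"] = nn.dropout_forward(X, p, rng)
    cache["X"] = X

    Hcat, cache["lstm"] = nn.bilstm_forward(X, state.params)
    contextual = Hcat
    if p > 0.0:
        Hcat, cache["drop_H"] = nn.dropout_forward(Hcat, p, rng)
    cache["Hcat"] = Hcat

    z_parts = []
    for k in cfg.kernel_sizes:
        Zk_pre, Xp = nn.conv1d_same_forward(
            Hcat, state.params[f"conv{k}_W"], state.params[f"conv{k}_b"]
        )
        cache[f"conv{k}_pre"] = Zk_pre
        cache[f"conv{k}_Xp"] = Xp
        z_parts.append(np.maximum(Zk_pre, 0.0))
    Z = np.concatenate(z_parts, axis=2) if len(z_parts) > 1 else z_parts[0]
    conv_features = Z
    if p > 0.0:
        Z, cache["drop_Z"] = nn.dropout_forward(Z, p, rng)
    cache["Z"] = Z

    logits = (Z @ state.params["dense_W"])[:, :, 0] + state.params["dense_b"][0]
    probs = nn.sigmoid(logits)
    out = ForwardOutput(contextual, conv_features, logits, probs)
    return out, cache


def backward(
    state: ModelState,
    batch: EncodedBatch,
    cache: dict,
    dlogits: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. every parameter, given dL/dlogits."""
    cfg = state.config
    params = state.params
    grads: dict[str, np.ndarray] = {}
    B, L = dlogits.shape
    C = cfg.total_conv_channels

    Z = cache["Z"]
    grads["dense_W"] = Z.reshape(B * L, C).T @ dlogits.reshape(B * L, 1)
    grads["dense_b"] = np.array([dlogits.sum()])
    dZ = dlogits[:, :, None] * params["dense_W"][:, 0]

    if "drop_Z" in cache:
        dZ = dZ * cache["drop_Z"]

    dHcat = np.zeros_like(cache["Hcat"])
    for j, k in enumerate(cfg.kernel_sizes):
        dZk = dZ[:, :, j * cfg.conv_channels:(j + 1) * cfg.conv_channels]
        dZk = dZk * (cache[f"conv{k}_pre"] > 0.0)
        dHk, dWk, dbk = nn.conv1d_same_backward(
            dZk, cache[f"conv{k}_Xp"], params[f"conv{k}_W"]
        )
        grads[f"conv{k}_W"] = dWk
        grads[f"conv{k}_b"] = dbk
        dHcat += dHk

    if "drop_H" in cache:
        dHcat = dHcat * cache["drop_H"]

    dX, lstm_grads = nn.bilstm_backward(dHcat, cache["lstm"], params)
    grads.update(lstm_grads)

    if "drop_X" in cache:
        dX = dX * cache["drop_X"]

    if cfg.encoding == "embedding":
        dE = np.zeros_like(params["embed"])
        np.add.at(dE, batch.indices, dX)
        grads["embed"] = dE
    return grads


def predict_residues(
    state: ModelState,
    batch: EncodedBatch,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> ForwardOutput:
    """Full forward pass; probabilities lie strictly inside (0, 1) at every
    position, padded ones included (downstream code masks them out)."""
    out, _ = _forward_full(state, batch, training, rng)
    return out


def bilstm_contextualize(
    state: ModelState,
    batch: EncodedBatch,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Contextual vectors h_t (B, L, 2H): forward and backward LSTM states
    concatenated per position, with dropout applied only in training mode."""
    cfg = state.config
    p = cfg.dropout_p if training else 0.0
    X = _input_features(state, batch)
    if p > 0.0 and cfg.dropout_embedding:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        X, _ = nn.dropout_forward(X, p, rng)
    Hcat, _ = nn.bilstm_forward(X, state.params)
    if p > 0.0:
        Hcat, _ = nn.dropout_forward(Hcat, p, rng)
    return Hcat


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Self-describing checkpoint: config + parameters + alphabet + version."""
    meta = {
        "format_version": CHECKPOINT_VERSION,
        "alphabet": ONEHOT_ALPHABET,
        "config": asdict(state.config),
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **state.params,
    )


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta['format_version']}"
            )
        if meta["alphabet"] != ONEHOT_ALPHABET:
            raise ValueError("checkpoint alphabet does not match this build")
        cfg_d = meta["config"]
        cfg_d["kernel_sizes"] = tuple(cfg_d["kernel_sizes"])
        config = ModelConfig(**cfg_d)
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return ModelState(config, params)
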