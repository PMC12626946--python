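"""Masked, class-weighted training with Adam and patience-based early stopping.

The loss is a per-residue binary cross-entropy in which the positive
(binding) class is up-weighted by ``w+ = N_neg / N_pos`` — the
negative-to-positive residue ratio of the *training* portion — and padded
positions are excluded by the mask.  The masked, weighted sum is divided by
the number of real residues so the reported loss is a mean and is invariant
to batch size; the normalization does not move the optimum.

Early stopping monitors the validation MCC by default (maximization) and
restores the parameters of the best epoch; monitoring the validation loss is
available as a configuration option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .data import LabeledChain, PaddedChain, pad_and_mask
from .encoding import EncodedBatch, encode
from .model import ModelConfig, ModelState, backward, init_model, _forward_full
from .nn import Adam
from .splits import REGIMES, SplitPlan, select_chain_regime

EPSILON = 1e-7  # clamp for log arguments


@dataclass(frozen=True)
class LossSpec:
    """Class weights for the masked binary cross-entropy."""

    w_plus: float
    w_minus: float = 1.0
    epsilon: float = EPSILON

    def __post_init__(self):
        if self.w_plus <= 0 or self.w_minus <= 0:
            raise ValueError("class weights must be positive")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 32
    early_stop_monitor: str = "val_mcc_max"  # or "val_loss_min"
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.early_stop_monitor not in ("val_mcc_max", "val_loss_min"):
            raise ValueError(f"unknown monitor {self.early_stop_monitor!r}")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)


def compute_class_weight(chains: Sequence[PaddedChain]) -> LossSpec:
    """w+ = N_neg / N_pos over the unpadded residues of the training chains."""
    n_pos = 0
    n_res = 0
    for pc in chains:
        n_pos += pc.chain.n_binding
        n_res += len(pc.chain)
    n_neg = n_res - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "degenerate training set: both classes must be present "
            f"(n_pos={n_pos}, n_neg={n_neg})"
        )
    return LossSpec(w_plus=n_neg / n_pos)


def masked_weighted_bce(
    probabilities: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    spec: LossSpec,
) -> float:
    """Mean masked weighted binary cross-entropy over real residues.

    loss = -(1/N) * sum_t m_t [ w+ y*_t log p_t + w- (1 - y*_t) log(1 - p_t) ]
    with N = number of real residues and log arguments clamped at epsilon.
    """
    p = np.clip(np.asarray(probabilities, dtype=float), spec.epsilon, 1.0 - spec.epsilon)
    y = np.asarray(labels, dtype=float)
    m = np.asarray(mask, dtype=float)
    n_real = m.sum()
    if n_real == 0:
        raise ValueError("all positions are masked; loss is undefined")
    terms = spec.w_plus * y * np.log(p) + spec.w_minus * (1.0 - y) * np.log(1.0 - p)
    return float(-(m * terms).sum() / n_real)


def bce_logit_gradient(
    probabilities: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    spec: LossSpec,
) -> np.ndarray:
    """d(mean masked weighted BCE)/d(logits), shape like ``probabilities``."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    m = np.asarray(mask, dtype=float)
    n_real = m.sum()
    return m * (spec.w_minus * (1.0 - y) * p - spec.w_plus * y * (1.0 - p)) / n_real


class EarlyStopper:
    """Patience counter with strict-improvement semantics.

    ``update`` returns True when the monitor failed to improve for
    ``patience`` consecutive epochs and training should stop.
    """

    def __init__(self, patience: int, mode: str):
        if mode not in ("max", "min"):
            raise ValueError("mode must be 'max' or 'min'")
        self.patience = patience
        self.mode = mode
        self.best: float | None = None
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, value: float) -> bool:
        improved = (
            self.best is None
            or (self.mode == "max" and value > self.best)
            or (self.mode == "min" and value < self.best)
        )
        if improved:
            self.best = value
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _prepare(
    chains: Sequence[LabeledChain], model_cfg: ModelConfig
) -> EncodedBatch:
    padded = [pad_and_mask(c, model_cfg.padded_length) for c in chains]
    return encode(padded, model_cfg.encoding)


def _batch_slices(batch: EncodedBatch, idx: np.ndarray) -> EncodedBatch:
    return EncodedBatch(
        encoding=batch.encoding,
        mask=batch.mask[idx],
        labels=batch.labels[idx],
        one_hot=None if batch.one_hot is None else batch.one_hot[idx],
        indices=None if batch.indices is None else batch.indices[idx],
    )


def _eval_probs(state: ModelState, batch: EncodedBatch) -> np.ndarray:
    out, _ = _forward_full(state, batch, training=False, rng=None)
    return out.probabilities


def train_model(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_chains: Sequence[LabeledChain],
    val_chains: Sequence[LabeledChain],
    loss_spec: LossSpec | None = None,
) -> tuple[ModelState, TrainHistory]:
    """Train the BiLSTM-CNN on ``train_chains``, early-stopping on
    ``val_chains``; returns the best-epoch parameters and the history.

    ``loss_spec`` defaults to the w+ = N_neg/N_pos weighting computed from
    the training chains; pass one explicitly to study other weightings.
    Train and validation chains must come from disjoint complexes; this is
    the caller's contract and is checked here by complex id.
    """
    if not train_chains or not val_chains:
        raise ValueError("train and validation chain sets must be non-empty")
    train_ids = {c.complex_id for c in train_chains}
    val_ids = {c.complex_id for c in val_chains}
    overlap = train_ids & val_ids
    if overlap:
        raise ValueError(f"complexes on both sides of the split: {sorted(overlap)[:5]}")

    padded_train = [pad_and_mask(c, model_cfg.padded_length) for c in train_chains]
    if loss_spec is None:
        loss_spec = compute_class_weight(padded_train)
    train_batch_all = encode(padded_train, model_cfg.encoding)
    val_batch = _prepare(val_chains, model_cfg)

    state = init_model(model_cfg)
    opt = Adam(list(state.params.keys()), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)
    stopper = EarlyStopper(
        train_cfg.patience,
        "max" if train_cfg.early_stop_monitor == "val_mcc_max" else "min",
    )
    history = TrainHistory()
    best_state = state.copy()
    n_train = train_batch_all.batch_size

    for epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_train, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            mb = _batch_slices(train_batch_all, idx)
            out, cache = _forward_full(state, mb, training=True, rng=rng)
            loss = masked_weighted_bce(out.probabilities, mb.labels, mb.mask, loss_spec)
            dlogits = bce_logit_gradient(out.probabilities, mb.labels, mb.mask, loss_spec)
            grads = backward(state, mb, cache, dlogits)
            opt.step(state.params, grads)
            epoch_loss += loss
            n_batches += 1

        val_probs = _eval_probs(state, val_batch)
        val_loss = masked_weighted_bce(val_probs, val_batch.labels, val_batch.mask, loss_spec)
        counts = _metrics.confusion_at_threshold(
            val_probs, val_batch.labels, val_batch.mask, train_cfg.threshold
        )
        panel = _metrics.metric_panel(counts)
        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / n_batches,
            "val_loss": val_loss,
            **{f"val_{k}": v for k, v in panel.items()},
        }
        history.epochs.append(record)

        monitor = (
            panel["mcc"]
            if train_cfg.early_stop_monitor == "val_mcc_max"
            else val_loss
        )
        should_stop = stopper.update(epoch, monitor)
        if stopper.best_epoch == epoch:
            best_state = state.copy()
        if should_stop:
            history.stop_reason = (
                f"no improvement in {train_cfg.early_stop_monitor} for "
                f"{train_cfg.patience} consecutive epochs"
            )
            break
    else:
        history.stop_reason = "max_epochs reached"

    history.best_epoch = stopper.best_epoch
    return best_state, history


# ---------------------------------------------------------------------------
# Configuration sweep
# ---------------------------------------------------------------------------

SWEEP_ENCODINGS = ("onehot", "embedding")
SWEEP_KERNELS = (7, 15, 31, 71, 130)


def enumerate_grid(
    encodings: Sequence[str] = SWEEP_ENCODINGS,
    regimes: Sequence[str] = REGIMES,
    kernel_sizes: Sequence[int] = SWEEP_KERNELS,
) -> list[dict]:
    """The full configuration grid: encodings x chain regimes x kernel sizes
    (2 x 3 x 5 = 30 configurations at the defaults)."""
    return [
        {"encoding": e, "regime": r, "kernel_size": k}
        for e, r, k in itertools.product(encodings, regimes, kernel_sizes)
    ]


def run_configuration_sweep(
    dataset,
    folds: SplitPlan,
    encodings: Sequence[str] = SWEEP_ENCODINGS,
    regimes: Sequence[str] = REGIMES,
    kernel_sizes: Sequence[int] = SWEEP_KERNELS,
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    dry_run: bool = False,
) -> pd.DataFrame:
    """Train every configuration on every fold; aggregate mean +- SD per
    metric and rank by mean MCC.

    With ``dry_run`` the planned runs are enumerated (one row per
    configuration x fold) without training — useful for sweep bookkeeping.
    """
    grid = enumerate_grid(encodings, regimes, kernel_sizes)
    k = len(folds.folds)

    if dry_run:
        rows = [
            {**cfg, "fold": fold}
            for cfg in grid
            for fold in range(k)
        ]
        return pd.DataFrame(rows)

    by_id = {c.complex_id: c for c in dataset}
    results = []
    for cfg in grid:
        mcfg = replace(
            state_encoding_update(model_cfg, cfg["encoding"]),
            kernel_sizes=(cfg["kernel_size"],),
        )
        fold_reports = []
        for fold in range(k):
            train_ids, val_ids = folds.fold_split(fold)
            train_chains = select_chain_regime(
                [by_id[i] for i in sorted(train_ids)], cfg["regime"]
            )
            val_chains = select_chain_regime(
                [by_id[i] for i in sorted(val_ids)], cfg["regime"]
            )
            state, _ = train_model(mcfg, train_cfg, train_chains, val_chains)
            val_batch = _prepare(val_chains, mcfg)
            probs = _eval_probs(state, val_batch)
            report = _metrics.full_report(
                probs, val_batch.labels, val_batch.mask, train_cfg.threshold,
                n_chains=len(val_chains),
            )
            fold_reports.append(report)
        agg = _metrics.aggregate_cv(fold_reports)
        row = {**cfg}
        for name, (mean, sd) in agg.items():
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
        results.append(row)
    frame = pd.DataFrame(results)
    return frame.sort_values("mcc_mean", ascending=False).reset_index(drop=True)


def state_encoding_update(cfg: ModelConfig, encoding: str) -> ModelConfig:
    return replace(cfg, encoding=encoding)
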