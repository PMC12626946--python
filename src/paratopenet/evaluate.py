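"""Blind-test evaluation harness with an explicit leakage guard, plus
cross-model comparison tables."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data import LabeledChain, LabeledDataset, pad_and_mask
from .encoding import encode
from .metrics import METRIC_ORDER, MetricsReport, full_report
from .model import ModelState, predict_residues
from .splits import select_chain_regime


def predict_chains(
    state: ModelState, chains: Sequence[LabeledChain]
) -> list[dict]:
    """Eval-mode per-residue predictions with padding stripped.

    Returns records suitable for :func:`paratopenet.data.write_predictions`.
    """
    padded = [pad_and_mask(c, state.config.padded_length) for c in chains]
    batch = encode(padded, state.config.encoding)
    out = predict_residues(state, batch, training=False)
    records = []
    for b, ch in enumerate(chains):
        n = len(ch)
        probs = out.probabilities[b, :n]
        records.append(
            {
                "complex_id": ch.complex_id,
                "chain_type": ch.chain_type,
                "sequence": ch.sequence,
                "probabilities": probs.tolist(),
                "calls": (probs >= 0.5).astype(int).tolist(),
            }
        )
    return records


def evaluate_blind(
    state: ModelState,
    blind: LabeledDataset | Sequence[LabeledChain],
    regime: str = "HL",
    threshold: float = 0.5,
    training_ids: Iterable[str] = (),
) -> MetricsReport:
    """Chain-regime-specific metric report on held-out chains.

    ``training_ids`` is the set of complex ids seen during training or
    tuning; any overlap with the blind complexes is a hard error (leakage
    guard).  Cross-regime evaluation (e.g. an H-trained model on L chains)
    is permitted and often informative.
    """
    if isinstance(blind, LabeledDataset):
        chains = select_chain_regime(blind, regime)
    else:
        chains = [c for c in blind if regime == "HL" or c.chain_type == regime]
    if not chains:
        raise ValueError(f"no chains to evaluate under regime {regime!r}")

    blind_ids = {c.complex_id for c in chains}
    overlap = blind_ids & set(training_ids)
    if overlap:
        raise ValueError(
            f"leakage: blind complexes also seen in training: {sorted(overlap)[:5]}"
        )

    padded = [pad_and_mask(c, state.config.padded_length) for c in chains]
    batch = encode(padded, state.config.encoding)
    out = predict_residues(state, batch, training=False)
    return full_report(
        out.probabilities, batch.labels, batch.mask, threshold,
        n_chains=len(chains),
    )


def comparison_table(reports: Mapping[str, MetricsReport]) -> pd.DataFrame:
    """One row per model, seven-metric panel in the conventional column
    order (AUC, PR AUC, accuracy, precision, recall, F1, MCC)."""
    rows = []
    for name, rep in reports.items():
        rows.append({"model": name, **rep.panel()})
    frame = pd.DataFrame(rows, columns=["model", *METRIC_ORDER])
    return frame
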