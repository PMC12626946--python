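"""Mask-aware, imbalance-robust evaluation: confusion counts, the
threshold panel (precision, recall, F1, accuracy, BAC, MCC) and the
threshold-free areas (ROC AUC, PR AUC).

Paratope labels are heavily imbalanced (~10% positive), so accuracy alone is
uninformative; MCC, balanced accuracy and PR AUC are the metrics that carry
the signal.  All computations pool real (unpadded) residues across chains
(micro-averaging); padded positions never enter.

Zero-division conventions follow the scikit-learn defaults: precision,
recall and F1 are 0 when their denominator is 0, and MCC is 0 when any
confusion-matrix marginal is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

METRIC_ORDER = (
    "roc_auc", "pr_auc", "accuracy", "precision", "recall", "f1", "mcc"
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """The seven-metric panel plus BAC and the underlying counts."""

    threshold: float
    counts: ConfusionCounts
    roc_auc: float
    pr_auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    bac: float
    mcc: float
    n_chains: int
    n_residues: int

    def panel(self) -> dict[str, float]:
        """Metrics in the conventional reporting order (AUC ... MCC)."""
        return {name: getattr(self, name) for name in METRIC_ORDER}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def _flatten_real(
    probabilities: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    m = np.asarray(mask)
    if not (p.shape == y.shape == m.shape):
        raise ValueError("probabilities, labels and mask must share a shape")
    real = m.astype(bool).ravel()
    if not real.any():
        raise ValueError("no real residues to evaluate (mask is all zero)")
    return p.ravel()[real], y.ravel()[real].astype(int)


def confusion_at_threshold(
    probabilities: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Confusion counts over real residues; call = 1 iff p >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    p, y = _flatten_real(probabilities, labels, mask)
    calls = p >= threshold
    pos = y == 1
    tp = int(np.sum(calls & pos))
    fp = int(np.sum(calls & ~pos))
    fn = int(np.sum(~calls & pos))
    tn = int(np.sum(~calls & ~pos))
    return ConfusionCounts(tp, fp, fn, tn)


def metric_panel(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, F1, accuracy, BAC and MCC from confusion counts."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    total = counts.total
    accuracy = (tp + tn) / total if total else 0.0
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    bac = 0.5 * (sens + spec)
    denom = (
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": accuracy,
        "bac": bac,
        "mcc": mcc,
    }


def _require_both_classes(y: np.ndarray, what: str) -> None:
    if y.min() == y.max():
        raise ValueError(
            f"{what} is undefined: only one class present among real residues"
        )


def roc_auc(
    probabilities: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> float:
    """ROC AUC over real residues (rank statistic; ties get half credit)."""
    p, y = _flatten_real(probabilities, labels, mask)
    _require_both_classes(y, "ROC AUC")
    return float(roc_auc_score(y, p))


def pr_auc(
    probabilities: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> float:
    """Area under the precision-recall curve (step integration) over real
    residues; always >= the positive-class prevalence for a sane ranker."""
    p, y = _flatten_real(probabilities, labels, mask)
    _require_both_classes(y, "PR AUC")
    return float(average_precision_score(y, p))


def full_report(
    probabilities: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    threshold: float = 0.5,
    n_chains: int | None = None,
) -> MetricsReport:
    """Assemble the complete report at one decision threshold."""
    counts = confusion_at_threshold(probabilities, labels, mask, threshold)
    panel = metric_panel(counts)
    return MetricsReport(
        threshold=threshold,
        counts=counts,
        roc_auc=roc_auc(probabilities, labels, mask),
        pr_auc=pr_auc(probabilities, labels, mask),
        n_chains=n_chains if n_chains is not None else int(np.asarray(mask).shape[0]),
        n_residues=counts.total,
        **panel,
    )


def aggregate_cv(fold_reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Mean and sample (n-1) standard deviation per metric across folds."""
    if len(fold_reports) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    out: dict[str, tuple[float, float]] = {}
    for name in METRIC_ORDER + ("bac",):
        vals = np.array([getattr(r, name) for r in fold_reports], dtype=float)
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out
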