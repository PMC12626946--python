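"""Complex-level data partitioning: blind hold-out, grouped stratified folds,
and chain-regime subsetting.

All splitting happens at the antibody-complex level, so the heavy and light
chain of one antibody always land on the same side of every split — the
leakage guard the whole evaluation protocol depends on.  Fold stratification
uses the per-complex binding-residue fraction, binned into quantiles, which
keeps the class balance (and hence the imbalance-sensitive metrics)
comparable across folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import AntibodyComplex, LabeledChain, LabeledDataset

REGIMES = ("H", "L", "HL")


@dataclass
class SplitPlan:
    """A frozen assignment of complex ids to the blind set and to k folds."""

    blind: set[str]
    folds: list[set[str]]
    seed: int
    stratification_key: str = "quartile-binned binding fraction"

    def validate(self) -> None:
        modeling = set().union(*self.folds) if self.folds else set()
        if self.blind & modeling:
            raise ValueError("blind and modeling sets overlap")
        n_total = sum(len(f) for f in self.folds)
        if n_total != len(modeling):
            raise ValueError("folds are not pairwise disjoint")

    def fold_split(self, fold: int) -> tuple[set[str], set[str]]:
        """(train ids, validation ids) with fold ``fold`` held out."""
        val = self.folds[fold]
        train = set().union(*(f for i, f in enumerate(self.folds) if i != fold))
        return train, val

    def save(self, path: str | Path) -> None:
        lines = [f"# seed={self.seed}", f"# stratification={self.stratification_key}"]
        for cid in sorted(self.blind):
            lines.append(f"blind\t{cid}")
        for i, fold in enumerate(self.folds):
            for cid in sorted(fold):
                lines.append(f"fold{i}\t{cid}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SplitPlan":
        blind: set[str] = set()
        folds: dict[int, set[str]] = {}
        seed = 0
        strat = ""
        for line in Path(path).read_text().splitlines():
            if line.startswith("# seed="):
                seed = int(line.split("=", 1)[1])
                continue
            if line.startswith("# stratification="):
                strat = line.split("=", 1)[1]
                continue
            if not line.strip() or line.startswith("#"):
                continue
            tag, cid = line.split("\t")
            if tag == "blind":
                blind.add(cid)
            elif tag.startswith("fold"):
                folds.setdefault(int(tag[4:]), set()).add(cid)
            else:
                raise ValueError(f"unknown split tag {tag!r}")
        plan = cls(blind, [folds[i] for i in sorted(folds)], seed, strat)
        plan.validate()
        return plan


def split_blind(
    ds: LabeledDataset, blind_fraction: float = 0.10, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Withhold round(n * blind_fraction) complexes as a blind test set.

    The draw is a seeded complex-level shuffle; both chains of a complex stay
    together by construction.
    """
    if not 0.0 < blind_fraction < 1.0:
        raise ValueError("blind_fraction must lie in (0, 1)")
    if len(ds) < 2:
        raise ValueError("need at least 2 complexes to split")
    ids = np.array(ds.complex_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_blind = round(len(ids) * blind_fraction)
    blind_ids = set(ids[order[:n_blind]])
    modeling = ds.subset(
        [i for i in ids if i not in blind_ids], note="modeling split"
    )
    blind = ds.subset(blind_ids, note="blind split")
    return modeling, blind


def _binding_fraction(cpx: AntibodyComplex) -> float:
    n_res = sum(len(c) for c in cpx.chains)
    n_bind = sum(c.n_binding for c in cpx.chains)
    return n_bind / n_res if n_res else 0.0


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-bin values; collapses duplicate edges gracefully."""
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), values, side="left")


def make_folds(
    modeling: LabeledDataset, k: int = 5, seed: int = 0
) -> SplitPlan:
    """k grouped, stratified folds over complexes (default 5, i.e. 80/20
    train/validation per fold).

    Stratification key: the per-complex binding-residue fraction, quartile
    binned.  If a bin is too sparse for k folds the number of bins is
    reduced until every class is feasible (a single bin degenerates to a
    plain seeded k-fold).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(modeling) < k:
        raise ValueError(f"need at least {k} complexes for {k} folds")
    ids = np.array(modeling.complex_ids)
    fracs = np.array([_binding_fraction(c) for c in modeling])

    n_bins = 4
    while n_bins > 1:
        bins = _quantile_bins(fracs, n_bins)
        if np.bincount(bins).min() >= k:
            break
        n_bins -= 1
    else:
        bins = np.zeros(len(ids), dtype=int)
    if n_bins == 1:
        bins = np.zeros(len(ids), dtype=int)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[set[str]] = []
    for _, val_idx in skf.split(ids, bins):
        folds.append(set(ids[val_idx]))
    plan = SplitPlan(set(), folds, seed)
    plan.validate()
    return plan


def select_chain_regime(
    ds: LabeledDataset | Sequence[AntibodyComplex], regime: str
) -> list[LabeledChain]:
    """Chains used under a training regime.

    H / L select one chain type; HL pools both chains of every complex as
    independent examples — chains are never concatenated per antibody.
    """
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
    chains: list[LabeledChain] = []
    for cpx in ds:
        if regime in ("H", "HL"):
            chains.append(cpx.heavy)
        if regime in ("L", "HL"):
            chains.append(cpx.light)
    return chains


def audit_leakage(plan: SplitPlan) -> None:
    """Exhaustive id audit: every complex id appears exactly once across
    blind + folds.  Raises on any violation."""
    seen: dict[str, str] = {}
    for cid in plan.blind:
        seen[cid] = "blind"
    for i, fold in enumerate(plan.folds):
        for cid in fold:
            if cid in seen:
                raise ValueError(
                    f"complex {cid} assigned to both {seen[cid]} and fold{i}"
                )
            seen[cid] = f"fold{i}"
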