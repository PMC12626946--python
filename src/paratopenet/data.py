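"""Labeled antibody chains, paired complexes, and their on-disk formats.

The unit of analysis is one antibody variable domain (heavy or light chain)
with a per-residue binary label: 1 where the residue contacts the antigen
(paratope residue), 0 elsewhere.  Chains are paired into complexes sharing a
``complex_id``; the complex is the grouping unit for every train/test split so
that the two chains of one antibody never end up on opposite sides of a split.

Native on-disk format is a 4-column TSV::

    complex_id <TAB> chain_type <TAB> sequence <TAB> labels

where ``labels`` is a string of '0'/'1' characters, one per residue.  An
auxiliary FASTA reader accepts records named ``<complex_id>_H`` /
``<complex_id>_L`` together with a label TSV mapping record id -> label string.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order; 'X' marks an
#: unknown residue and is the only other letter a validated chain may contain.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"
ALPHABET = STANDARD_AA + UNKNOWN_AA

CHAIN_TYPES = ("H", "L")


class ChainRecordError(ValueError):
    """A malformed chain record (e.g. sequence/label length mismatch)."""


@dataclass(frozen=True)
class LabeledChain:
    """One antibody chain with per-residue binding labels."""

    complex_id: str
    chain_type: str  # "H" or "L"
    sequence: str
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.chain_type not in CHAIN_TYPES:
            raise ChainRecordError(
                f"{self.complex_id}: chain_type must be 'H' or 'L', got {self.chain_type!r}"
            )
        if len(self.sequence) != len(self.labels):
            raise ChainRecordError(
                f"{self.complex_id}/{self.chain_type}: sequence length "
                f"{len(self.sequence)} != label length {len(self.labels)}"
            )
        if any(lab not in (0, 1) for lab in self.labels):
            raise ChainRecordError(
                f"{self.complex_id}/{self.chain_type}: labels must be 0 or 1"
            )
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ChainRecordError(
                f"{self.complex_id}/{self.chain_type}: residues outside the "
                f"21-letter alphabet: {sorted(bad)} (normalize to 'X' first)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_binding(self) -> int:
        return sum(self.labels)


@dataclass(frozen=True)
class AntibodyComplex:
    """A paired heavy + light chain sharing one complex identifier."""

    complex_id: str
    heavy: LabeledChain
    light: LabeledChain

    def __post_init__(self) -> None:
        if self.heavy.chain_type != "H" or self.light.chain_type != "L":
            raise ChainRecordError(f"{self.complex_id}: chains must be typed H and L")
        if not (self.heavy.complex_id == self.light.complex_id == self.complex_id):
            raise ChainRecordError(
                f"{self.complex_id}: paired chains carry mismatched complex_ids"
            )

    @property
    def chains(self) -> tuple[LabeledChain, LabeledChain]:
        return (self.heavy, self.light)


@dataclass
class LabeledDataset:
    """An ordered collection of antibody complexes plus provenance metadata."""

    complexes: list[AntibodyComplex]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.complex_id for c in self.complexes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ChainRecordError(f"duplicate complex_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[AntibodyComplex]:
        return iter(self.complexes)

    @property
    def complex_ids(self) -> list[str]:
        return [c.complex_id for c in self.complexes]

    def chains(self) -> list[LabeledChain]:
        out: list[LabeledChain] = []
        for c in self.complexes:
            out.extend(c.chains)
        return out

    def subset(self, ids: Iterable[str], note: str = "subset") -> "LabeledDataset":
        wanted = set(ids)
        kept = [c for c in self.complexes if c.complex_id in wanted]
        prov = dict(self.provenance)
        prov["filter"] = note
        return LabeledDataset(kept, prov)


@dataclass(frozen=True)
class PaddedChain:
    """A chain right-padded to a fixed length with an explicit mask.

    ``mask[t] == 1`` marks a real residue, 0 marks padding; the mask is a
    prefix of ones.  Labels at padded positions are 0 and must never reach the
    loss or the metrics.
    """

    chain: LabeledChain
    padded_length: int
    mask: tuple[int, ...]
    padded_labels: tuple[int, ...]


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and map non-standard letters to 'X'.

    Returns the normalized sequence and the number of residues rewritten.
    Covers ambiguity codes (B, Z, J), the rare residues U/O, stops ('*') and
    anything else outside the 20-letter alphabet.
    """
    out = []
    n_subst = 0
    for ch in seq.upper():
        if ch in STANDARD_AA:
            out.append(ch)
        else:
            out.append(UNKNOWN_AA)
            if ch != UNKNOWN_AA:
                n_subst += 1
    return "".join(out), n_subst


def _pair_chains(
    chains: Sequence[LabeledChain], provenance: dict
) -> LabeledDataset:
    by_complex: dict[str, dict[str, LabeledChain]] = {}
    for ch in chains:
        slot = by_complex.setdefault(ch.complex_id, {})
        if ch.chain_type in slot:
            raise ChainRecordError(
                f"{ch.complex_id}: duplicate {ch.chain_type} chain record"
            )
        slot[ch.chain_type] = ch
    complexes: list[AntibodyComplex] = []
    excluded: list[str] = []
    for cid, slot in by_complex.items():
        if "H" in slot and "L" in slot:
            complexes.append(AntibodyComplex(cid, slot["H"], slot["L"]))
        else:
            excluded.append(cid)
    if excluded:
        log.warning(
            "%d complex(es) missing a chain were excluded: %s",
            len(excluded), ", ".join(excluded[:10]),
        )
    provenance["n_excluded_incomplete"] = len(excluded)
    provenance["excluded_incomplete_ids"] = excluded
    return LabeledDataset(complexes, provenance)


def _parse_labels(cid: str, ctype: str, seq: str, labels: str) -> LabeledChain:
    if len(labels) != len(seq):
        raise ChainRecordError(
            f"record {cid}/{ctype}: sequence length {len(seq)} != "
            f"label string length {len(labels)}"
        )
    if set(labels) - {"0", "1"}:
        raise ChainRecordError(f"record {cid}/{ctype}: labels must be '0'/'1'")
    norm, _ = normalize_sequence(seq)
    return LabeledChain(cid, ctype, norm, tuple(int(c) for c in labels))


def read_chain_table(
    path: str | Path,
    format: str = "tsv",
    labels: str | Path | None = None,
) -> LabeledDataset:
    """Read labeled chains from disk and pair them into complexes.

    Parameters
    ----------
    path:
        TSV file (``format="tsv"``) or FASTA file (``format="fasta_pair"``).
    format:
        ``"tsv"``: 4 columns per row (complex_id, chain_type, sequence,
        labels-as-'0'/'1'-string); a header row starting with ``complex_id``
        and ``#`` comment lines are skipped.
        ``"fasta_pair"``: FASTA records named ``<complex_id>_<H|L>``; the
        ``labels`` argument names a 2-column TSV mapping record id to a
        '0'/'1' label string.
    labels:
        Label TSV, required for ``fasta_pair``.

    Complexes missing either chain are excluded (counted in provenance);
    malformed records raise :class:`ChainRecordError` naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    prov: dict = {"source": str(path), "format": format}
    n_subst_total = 0
    chains: list[LabeledChain] = []

    if format == "tsv":
        with open(path) as fh:
            rows = [
                line.rstrip("\n") for line in fh
                if line.strip() and not line.startswith("#")
            ]
        if rows and rows[0].split("\t")[0].lower() == "complex_id":
            rows = rows[1:]
        if not rows:
            raise ChainRecordError(f"{path}: no chain records found")
        for i, row in enumerate(rows, start=1):
            fields = row.split("\t")
            if len(fields) != 4:
                raise ChainRecordError(f"{path} line {i}: expected 4 columns")
            cid, ctype, seq, labstr = (f.strip() for f in fields)
            _, n_subst = normalize_sequence(seq)
            n_subst_total += n_subst
            chains.append(_parse_labels(cid, ctype, seq, labstr))
    elif format == "fasta_pair":
        if labels is None:
            raise ValueError("fasta_pair format requires a labels file")
        from Bio import SeqIO

        label_map: dict[str, str] = {}
        with open(labels) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                rid, labstr = line.split("\t")[:2]
                label_map[rid.strip()] = labstr.strip()
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ChainRecordError(f"{path}: no FASTA records found")
        for rec in records:
            rid = rec.id
            if "_" not in rid or rid.rsplit("_", 1)[1] not in CHAIN_TYPES:
                raise ChainRecordError(
                    f"FASTA id {rid!r} does not match '<complex_id>_H/L'"
                )
            cid, ctype = rid.rsplit("_", 1)
            if rid not in label_map:
                raise ChainRecordError(f"record {rid}: no label string provided")
            seq = str(rec.seq)
            _, n_subst = normalize_sequence(seq)
            n_subst_total += n_subst
            chains.append(_parse_labels(cid, ctype, seq, label_map[rid]))
    else:
        raise ValueError(f"unknown format {format!r}")

    if n_subst_total:
        log.warning("%d non-standard residue(s) normalized to 'X'", n_subst_total)
    prov["n_residues_normalized_to_X"] = n_subst_total
    return _pair_chains(chains, prov)


def write_chain_table(ds: LabeledDataset, path: str | Path) -> None:
    """Write a dataset in the native 4-column TSV format."""
    with open(path, "w") as fh:
        fh.write("complex_id\tchain_type\tsequence\tlabels\n")
        for cpx in ds:
            for ch in cpx.chains:
                labstr = "".join(str(v) for v in ch.labels)
                fh.write(f"{ch.complex_id}\t{ch.chain_type}\t{ch.sequence}\t{labstr}\n")


def filter_by_length(
    ds: LabeledDataset, min_len: int = 110, max_len: int = 130
) -> LabeledDataset:
    """Keep complexes whose chains BOTH have length in [min_len, max_len].

    The bounds are inclusive and target the typical span of antibody variable
    domains; shorter entries are usually incomplete structures and longer ones
    include constant-domain residues.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = [
        c for c in ds
        if all(min_len <= len(ch) <= max_len for ch in c.chains)
    ]
    prov = dict(ds.provenance)
    prov["length_filter"] = (min_len, max_len)
    prov["n_removed_by_length"] = len(ds) - len(kept)
    return LabeledDataset(kept, prov)


def pad_and_mask(chain: LabeledChain, padded_length: int = 130) -> PaddedChain:
    """Right-pad a chain to ``padded_length``; mask marks the real residues."""
    n = len(chain)
    if n > padded_length:
        raise ValueError(
            f"{chain.complex_id}/{chain.chain_type}: length {n} exceeds padded "
            f"length {padded_length}; apply filter_by_length first"
        )
    mask = (1,) * n + (0,) * (padded_length - n)
    padded_labels = chain.labels + (0,) * (padded_length - n)
    return PaddedChain(chain, padded_length, mask, padded_labels)


def dataset_summary(ds: LabeledDataset) -> dict:
    """Residue-level composition of a dataset, overall and per chain type.

    ``binding_fraction`` is n_binding / n_residues over real (unpadded)
    residues only.
    """
    if len(ds) == 0:
        raise ValueError("cannot summarize an empty dataset")
    chains = ds.chains()

    def _block(sub: Sequence[LabeledChain]) -> dict:
        n_res = sum(len(c) for c in sub)
        n_bind = sum(c.n_binding for c in sub)
        return {
            "n_chains": len(sub),
            "n_residues": n_res,
            "n_binding": n_bind,
            "binding_fraction": (n_bind / n_res) if n_res else 0.0,
        }

    summary = {
        "n_complexes": len(ds),
        **_block(chains),
        "per_chain_type": {
            t: _block([c for c in chains if c.chain_type == t])
            for t in CHAIN_TYPES
        },
    }
    return summary


def write_predictions(records: Iterable[Mapping], path: str | Path) -> None:
    """Write per-residue predictions as a TSV.

    Each record maps ``complex_id, chain_type, sequence, probabilities,
    calls``; probabilities and calls carry one entry per real residue
    (padding already stripped).  Positions are reported 1-based.
    """
    buf = io.StringIO()
    buf.write("complex_id\tchain_type\tposition\tresidue\tprobability\tcall\n")
    for rec in records:
        seq = rec["sequence"]
        probs = rec["probabilities"]
        calls = rec["calls"]
        if len(probs) != len(seq) or len(calls) != len(seq):
            raise ValueError(
                f"{rec['complex_id']}/{rec['chain_type']}: probabilities/calls "
                "must have one entry per residue"
            )
        for pos, (aa, p, call) in enumerate(zip(seq, probs, calls), start=1):
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"{rec['complex_id']}/{rec['chain_type']} position {pos}: "
                    f"probability {p} outside [0, 1]"
                )
            buf.write(
                f"{rec['complex_id']}\t{rec['chain_type']}\t{pos}\t{aa}\t"
                f"{p:.6f}\t{int(call)}\n"
            )
    Path(path).write_text(buf.getvalue())


def read_predictions(path: str | Path) -> list[dict]:
    """Parse a prediction TSV back into per-chain records (round-trip of
    :func:`write_predictions`)."""
    groups: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("complex_id"):
            raise ValueError(f"{path}: missing prediction header")
        for line in fh:
            cid, ctype, pos, aa, prob, call = line.rstrip("\n").split("\t")
            key = (cid, ctype)
            g = groups.setdefault(
                key,
                {"complex_id": cid, "chain_type": ctype, "sequence": "",
                 "probabilities": [], "calls": []},
            )
            if int(pos) != len(g["sequence"]) + 1:
                raise ValueError(f"{path}: positions out of order for {key}")
            g["sequence"] += aa
            g["probabilities"].append(float(prob))
            g["calls"].append(int(call))
    return list(groups.values())
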