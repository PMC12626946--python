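"""Synthetic antibody-like paired-chain datasets with planted binding motifs.

The generator emulates the statistics the predictor is built for: paired H/L
chains of 110-130 residues, ~10% positive residues concentrated in a few
short contiguous loop segments per chain, and a stronger sequence signal on
the heavy chain.  The planted signal is purely compositional: binding
residues are drawn, with probability ``motif_strength``, from a biased
distribution over paratope-prone residues (aromatics and arginine) instead
of the uniform background.  Loop segments are placed uniformly at random
along the chain, so residue composition is the *only* label signal; at
motif strength 0 the labels carry no sequence information at all, which
gives a clean null control for any learner evaluated on this data.

Heavy chains route their surplus binding residues to the last loop (a
CDR-H3 analog, typically the longest) and carry a higher default motif
strength, emulating the empirical observation that heavy chains are more
learnable from sequence than light chains.  This is a test-bed
convenience, not a biological claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AntibodyComplex, LabeledChain, LabeledDataset, STANDARD_AA

#: Residues enriched in the planted binding loops, with draw probabilities.
#: Tyr/Trp/Arg are genuinely over-represented in real paratopes, which keeps
#: the synthetic signal biologically flavoured.
BIASED_RESIDUES = ("Y", "W")
BIASED_PROBS = (0.6, 0.4)

#: Conserved residue planted immediately before and after each loop, the
#: analog of the invariant cysteines/tryptophan anchoring real CDR loops.
ANCHOR_RESIDUE = "C"

_MIN_LOOP = 3  # shortest plantable loop segment


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    ``positive_fraction`` fixes the binding-residue budget per chain
    (round(fraction * length)); that budget is partitioned into
    ``n_loops`` contiguous segments, with heavy chains preferentially
    routing the surplus to their last, longest segment (CDR-H3 analog).
    ``motif_strength_h`` / ``motif_strength_l`` give the
    probability that a binding residue is drawn from the biased
    distribution instead of the uniform background, per chain type.
    """

    n_complexes: int = 200
    length_range: tuple[int, int] = (110, 130)
    n_loops: int = 3
    max_loop_len: int = 12
    positive_fraction: float = 0.104
    motif_strength_h: float = 0.9
    motif_strength_l: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_complexes < 1:
            raise ValueError("n_complexes must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi <= 130):
            raise ValueError("length_range must lie within [1, 130]")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        for s in (self.motif_strength_h, self.motif_strength_l):
            if not 0.0 <= s <= 1.0:
                raise ValueError("motif strengths must lie in [0, 1]")
        if self.n_loops < 1:
            raise ValueError("n_loops must be >= 1")


def _loop_lengths(
    rng: np.random.Generator, n_pos: int, n_loops: int, cap: int, h3: bool
) -> list[int]:
    """Partition ``n_pos`` binding residues into ``n_loops`` segment lengths
    within [_MIN_LOOP, cap].  With ``h3`` the last segment preferentially
    receives the surplus (the CDR-H3 analog)."""
    if not (n_loops * _MIN_LOOP <= n_pos <= n_loops * cap):
        raise ValueError(
            f"positive budget {n_pos} unreachable with {n_loops} loops of "
            f"length {_MIN_LOOP}..{cap}"
        )
    parts = [_MIN_LOOP] * n_loops
    remaining = n_pos - n_loops * _MIN_LOOP
    while remaining > 0:
        if h3 and parts[-1] < cap and rng.random() < 0.6:
            idx = n_loops - 1
        else:
            open_idx = [i for i in range(n_loops) if parts[i] < cap]
            idx = open_idx[rng.integers(len(open_idx))]
        parts[idx] += 1
        remaining -= 1
    return parts


def _place_loops(
    rng: np.random.Generator, length: int, parts: list[int]
) -> list[tuple[int, int]]:
    """Uniform non-overlapping placement of loop segments (>= 1 residue gap
    between consecutive segments).  Returns [start, end) windows."""
    n = len(parts)
    slack = length - sum(parts) - (n - 1)  # free gap residues beyond the minimum
    if slack < 0:
        raise ValueError("loops do not fit in the chain")
    # gaps drawn uniformly over all compositions of the slack (stars and
    # bars), i.e. uniformly over every valid non-overlapping placement --
    # any clumpier sampler would plant positional label signal
    if slack > 0:
        cuts = np.sort(rng.choice(slack + n, size=n, replace=False))
        extra = np.diff(np.concatenate([[-1], cuts, [slack + n]])) - 1
    else:
        extra = np.zeros(n + 1, dtype=int)
    windows = []
    pos = extra[0]
    for i, p in enumerate(parts):
        windows.append((pos, pos + p))
        pos += p + extra[i + 1] + (1 if i < n - 1 else 0)
    return windows


def _synthesize_chain(
    rng: np.random.Generator,
    complex_id: str,
    chain_type: str,
    spec: GeneratorSpec,
) -> LabeledChain:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    n_pos = round(spec.positive_fraction * length)
    is_h = chain_type == "H"
    n_loops = spec.n_loops
    strength = spec.motif_strength_h if is_h else spec.motif_strength_l

    parts = _loop_lengths(rng, n_pos, n_loops, spec.max_loop_len, h3=is_h)
    windows = _place_loops(rng, length, parts)

    labels = np.zeros(length, dtype=int)
    for start, end in windows:
        labels[start:end] = 1

    aa = np.array(list(STANDARD_AA))
    seq = aa[rng.integers(0, len(aa), size=length)]
    biased = np.array(BIASED_RESIDUES)
    for t in np.flatnonzero(labels):
        if rng.random() < strength:
            seq[t] = biased[rng.choice(len(biased), p=np.array(BIASED_PROBS))]
    # conserved anchor residues flanking each loop (CDR-anchor analog);
    # planted with the same strength so they vanish in the null control
    for start, end in windows:
        if start > 0 and labels[start - 1] == 0 and rng.random() < strength:
            seq[start - 1] = ANCHOR_RESIDUE
        if end < length and labels[end] == 0 and rng.random() < strength:
            seq[end] = ANCHOR_RESIDUE
    return LabeledChain(complex_id, chain_type, "".join(seq), tuple(labels))


def generate_dataset(spec: GeneratorSpec) -> LabeledDataset:
    """Generate a fully reproducible paired-chain dataset from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    complexes = []
    for i in range(spec.n_complexes):
        cid = f"SYN{i:04d}"
        heavy = _synthesize_chain(rng, cid, "H", spec)
        light = _synthesize_chain(rng, cid, "L", spec)
        complexes.append(AntibodyComplex(cid, heavy, light))
    prov = {
        "source": "paratopenet.simulate.generate_dataset",
        "spec": repr(spec),
    }
    return LabeledDataset(complexes, prov)


# ---------------------------------------------------------------------------
# Hand-written micro example (fixture for exact-value unit tests)
# ---------------------------------------------------------------------------

# Two complexes, four chains; sequences are germline-flavoured variable
# domains (synthetic, hand-written), labels mark hand-chosen CDR-like loop
# windows.  Lengths are within [110, 130]; 98 of 462 residues are positive.
_MICRO_CHAINS = [
    # (complex_id, chain_type, sequence, labels)
    (
        "demo1", "H",
        "EVQLVESGGGLVQPGGSLRLSCAASGFTFSSYAMSWVRQAPGKGLEWVSAISGSGGSTYY"
        "ADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAKDRGYYFDYWGQGTLVTVSS",
        "000000000000000000000000001111111100000000000000001111111100"
        "000000000000000000000000000000000000011111111110000000000",
    ),
    (
        "demo1", "L",
        "DIQMTQSPSSLSASVGDRVTITCRASQSISSYLNWYQQKPGKAPKLLIYAASSLQSGVPS"
        "RFSGSGSGTDFTLTISSLQPEDFATYYCQQSYSTPLTFGQGTKVEIKRTVAAPS",
        "000000000000000000000000111111111100000000000000011100000000"
        "000000000000000000000000000001111111100000000000000000",
    ),
    (
        "demo2", "H",
        "QVQLQESGPGLVKPSETLSLTCTVSGGSISSYYWSWIRQPPGKGLEWIGYIYYSGSTNYN"
        "PSLKSRVTISVDTSKNQFSLKLSSVTAADTAVYYCARGGYYWYFDLWGRGTLVTVSS",
        "000000000000000000000000001111111110000000000000011111111000"
        "000000000000000000000000000000000000111111111110000000000",
    ),
    (
        "demo2", "L",
        "EIVLTQSPGTLSLSPGERATLSCRASQSVSSSYLAWYQQKPGQAPRLLIYGASSRATGIP"
        "DRFSGSGSGTDFTLTISRLEPEDFAVYYCQQYGSSPWTFGQGTKVEIKRTVAAP",
        "000000000000000000000001111111111100000000000000001110000000"
        "000000000000000000000000000001111111110000000000000000",
    ),
]

#: Binding fraction of the micro example (98 / 462), asserted by its own
#: unit test via dataset_summary.
MICRO_EXAMPLE_BINDING_FRACTION = 98 / 462


def generate_worked_micro_example() -> LabeledDataset:
    """Fixed two-complex dataset used by I/O, padding, loss and metric tests."""
    chains = [
        LabeledChain(cid, ctype, seq, tuple(int(c) for c in labels))
        for cid, ctype, seq, labels in _MICRO_CHAINS
    ]
    complexes = [
        AntibodyComplex("demo1", chains[0], chains[1]),
        AntibodyComplex("demo2", chains[2], chains[3]),
    ]
    return LabeledDataset(complexes, {"source": "worked micro example"})
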