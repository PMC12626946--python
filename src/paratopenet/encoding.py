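"""Numeric residue representations: 21-dim one-hot vectors or integer indices.

Two schemes are supported and compared throughout the package:

* **one-hot** — each residue becomes a binary vector of length 21 (the 20
  standard amino acids plus 'X' as a real 21st category); padded positions are
  all-zero rows.
* **indices** — residues map to integers 1..20 in the fixed alphabet order,
  with index 0 shared by padding and the unknown residue 'X'.  The index
  stream feeds a learnable embedding table.

The asymmetry ('X' is its own one-hot category but shares token 0 with
padding in the index scheme) is deliberate and preserved by both encoders.
The alphabet ordering is fixed and published so saved models stay portable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import PaddedChain, STANDARD_AA, UNKNOWN_AA

#: Fixed alphabet ordering used by every encoder and checkpoint.
ONEHOT_ALPHABET = STANDARD_AA + UNKNOWN_AA  # 21 letters, 'X' last
ONEHOT_DIM = len(ONEHOT_ALPHABET)  # 21

_ONEHOT_INDEX = {aa: i for i, aa in enumerate(ONEHOT_ALPHABET)}
#: indices 1..20 for the standard letters; 0 = padding-or-unknown token.
_TOKEN_INDEX = {aa: i + 1 for i, aa in enumerate(STANDARD_AA)}
_TOKEN_INDEX[UNKNOWN_AA] = 0
PAD_TOKEN = 0
N_TOKENS = 21  # tokens 0..20


@dataclass
class EncodedBatch:
    """Fixed-length numeric batch: residues, mask and labels.

    Exactly one of ``one_hot`` (B, L, 21) / ``indices`` (B, L) is set,
    according to ``encoding``.  ``mask`` and ``labels`` are (B, L) float
    arrays taken verbatim from the source padded chains.
    """

    encoding: str  # "onehot" | "embedding"
    mask: np.ndarray
    labels: np.ndarray
    one_hot: np.ndarray | None = None
    indices: np.ndarray | None = None

    @property
    def batch_size(self) -> int:
        return self.mask.shape[0]

    @property
    def padded_length(self) -> int:
        return self.mask.shape[1]

    @property
    def feature_dim(self) -> int:
        return ONEHOT_DIM


def _check_common(chains: Sequence[PaddedChain]) -> int:
    if not chains:
        raise ValueError("cannot encode an empty chain collection")
    lengths = {c.padded_length for c in chains}
    if len(lengths) != 1:
        raise ValueError(f"chains must share padded_length, got {sorted(lengths)}")
    return lengths.pop()


def _mask_labels(chains: Sequence[PaddedChain], L: int) -> tuple[np.ndarray, np.ndarray]:
    mask = np.zeros((len(chains), L))
    labels = np.zeros((len(chains), L))
    for b, pc in enumerate(chains):
        mask[b] = pc.mask
        labels[b] = pc.padded_labels
    return mask, labels


def encode_one_hot(chains: Sequence[PaddedChain]) -> EncodedBatch:
    """Encode padded chains as (B, L, 21) one-hot arrays.

    Real positions have exactly one 1; padded positions are zero vectors.
    """
    L = _check_common(chains)
    X = np.zeros((len(chains), L, ONEHOT_DIM))
    for b, pc in enumerate(chains):
        for t, aa in enumerate(pc.chain.sequence):
            try:
                X[b, t, _ONEHOT_INDEX[aa]] = 1.0
            except KeyError:
                raise ValueError(
                    f"residue {aa!r} outside the 21-letter alphabet"
                ) from None
    mask, labels = _mask_labels(chains, L)
    return EncodedBatch("onehot", mask, labels, one_hot=X)


def encode_indices(chains: Sequence[PaddedChain]) -> EncodedBatch:
    """Encode padded chains as (B, L) integer token arrays.

    Standard residues map to 1..20; 'X' and padding both map to token 0.
    """
    L = _check_common(chains)
    idx = np.zeros((len(chains), L), dtype=np.int64)
    for b, pc in enumerate(chains):
        for t, aa in enumerate(pc.chain.sequence):
            try:
                idx[b, t] = _TOKEN_INDEX[aa]
            except KeyError:
                raise ValueError(
                    f"residue {aa!r} outside the 21-letter alphabet"
                ) from None
    mask, labels = _mask_labels(chains, L)
    return EncodedBatch("embedding", mask, labels, indices=idx)


def decode_index(token: int) -> str:
    """Inverse of the index map for tokens 1..20; token 0 decodes to 'X'."""
    if token == PAD_TOKEN:
        return UNKNOWN_AA
    if not 1 <= token <= 20:
        raise ValueError(f"token {token} outside [0, 20]")
    return STANDARD_AA[token - 1]


def encode(chains: Sequence[PaddedChain], encoding: str) -> EncodedBatch:
    """Dispatch on the configured encoding scheme."""
    if encoding == "onehot":
        return encode_one_hot(chains)
    if encoding == "embedding":
        return encode_indices(chains)
    raise ValueError(f"unknown encoding {encoding!r}")
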