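import numpy as np
import pytest

import paratopenet as pn
from paratopenet.data import LabeledChain, pad_and_mask
from paratopenet.encoding import encode
from paratopenet.model import ModelConfig


@pytest.fixture(scope="session")
def micro_dataset():
    """The hand-written two-complex fixture."""
    return pn.generate_worked_micro_example()


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-complex synthetic dataset at generator defaults."""
    return pn.generate_dataset(pn.GeneratorSpec(n_complexes=60, seed=7))


@pytest.fixture
def tiny_config():
    """A model small enough for brute-force and finite-difference checks."""
    return ModelConfig(
        encoding="onehot",
        hidden_size=2,
        kernel_sizes=(3,),
        conv_channels=2,
        dropout_p=0.0,
        padded_length=6,
        seed=3,
    )


@pytest.fixture
def tiny_batch():
    chains = [
        LabeledChain("a", "H", "ACDYW", (0, 1, 1, 0, 0)),
        LabeledChain("b", "L", "WYX", (1, 0, 1)),
    ]
    padded = [pad_and_mask(c, 6) for c in chains]
    return encode(padded, "onehot")


def write_tsv(path, rows):
    """Helper: write a chain-table TSV from (cid, ctype, seq, labels) rows."""
    lines = ["complex_id\tchain_type\tsequence\tlabels"]
    lines += ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
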