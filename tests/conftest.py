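import numpy as np
import pytest

from alleracc.descriptors import EDescriptorTable, load_e_descriptor_table
from alleracc.io import CANONICAL_ALPHABET, ProteinRecord, SequenceDataset

ALPHABET = sorted(CANONICAL_ALPHABET)


@pytest.fixture(scope="session")
def shipped_table():
    return load_e_descriptor_table()


@pytest.fixture()
def random_table():
    """A random but fixed 20x5 descriptor table for oracle comparisons."""
    rng = np.random.default_rng(42)
    return EDescriptorTable(
        entries={c: rng.normal(size=5) for c in ALPHABET},
        source="random test table", checksum="",
    )


def make_dataset(sequences, labels=None, prefix="rec"):
    return SequenceDataset(
        records=[ProteinRecord(id=f"{prefix}{i}", sequence=s)
                 for i, s in enumerate(sequences)],
        labels=labels,
    )


def random_sequence(rng, length):
    return "".join(rng.choice(ALPHABET, size=length))
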