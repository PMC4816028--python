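import random

import pytest

from sarmap.index import ReferenceIndex, load_reference


def write_fasta(path, records):
    """records: list of (name, sequence) tuples."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def make_reference(tmp_path):
    """Factory: build a ReferenceGenome from (name, seq) pairs via FASTA."""

    def _make(records, filename="ref.fa"):
        return load_reference(write_fasta(tmp_path / filename, records))

    return _make


@pytest.fixture
def make_index(make_reference):
    """Factory: build a full index from (name, seq) pairs with small k."""

    def _make(records, k=4):
        return ReferenceIndex.build(make_reference(records), k=k)

    return _make


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
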