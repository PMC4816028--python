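"""Seed generation and exact seed placement via the suffix-array index.

Reads are split into a fixed number of seeds distributed uniformly along
the read, each searched exactly against the forward-strand index; the
reverse strand is handled by also searching the seeds of the
reverse-complemented read, so hit coordinates for reverse-strand hits are
expressed in reverse-complement ("strand-oriented") read coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .index import ReferenceIndex, sa_search

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


@dataclass
class Read:
    """A single-end read with per-base qualities."""

    id: str
    sequence: str
    qualities: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Seed:
    read_offset: int  # 0-based start within the (strand-oriented) read
    length: int


@dataclass(frozen=True)
class SeedHit:
    seed: Seed
    genome_offset: int  # 0-based offset in the concatenated genome
    strand: str  # '+' or '-'


def generate_seeds(read: Read, seed_length: int, num_seeds: int) -> list[Seed]:
    """Place ``num_seeds`` seeds of ``seed_length`` uniformly along the read.

    Start offsets follow round(i*(L-s)/(n-1)) with round-half-even
    rounding; duplicates collapse, a read shorter than the seed yields one
    whole-read seed, and for n >= 2 the first seed starts at 0 and the
    last ends at the read end.
    """
    if seed_length < 1 or num_seeds < 1:
        raise ValueError("seed_length and num_seeds must be >= 1")
    length = len(read)
    if length < seed_length:
        return [Seed(0, length)]
    if num_seeds == 1:
        return [Seed(0, seed_length)]
    span = length - seed_length
    starts: list[int] = []
    for i in range(num_seeds):
        start = round(i * span / (num_seeds - 1))
        if not starts or start != starts[-1]:
            starts.append(start)
    return [Seed(s, seed_length) for s in starts]


def default_num_seeds(read_length: int, seed_length: int) -> int:
    """More seeds for longer reads: n = max(5, floor(L / s))."""
    return max(5, read_length // seed_length)


def map_seeds(
    read: Read,
    index: ReferenceIndex,
    seed_length: int | None = None,
    num_seeds: int | None = None,
    max_hits_per_seed: int = 100,
) -> list[SeedHit]:
    """Locate exact occurrences of every seed on both strands.

    Seeds containing N are skipped, and a seed with more than
    ``max_hits_per_seed`` occurrences contributes no hits at all (repeat
    masking).  Reverse-strand hits carry seed offsets in the
    reverse-complemented read's coordinates.
    """
    s = seed_length if seed_length is not None else index.ptable.k
    n = num_seeds if num_seeds is not None else default_num_seeds(len(read), s)
    seeds = generate_seeds(read, s, n)
    hits: list[SeedHit] = []
    for strand, oriented in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        for seed in seeds:
            sub = oriented[seed.read_offset : seed.read_offset + seed.length]
            if "N" in sub:
                continue
            offsets = sa_search(sub, index)
            if not offsets or len(offsets) > max_hits_per_seed:
                continue
            hits.extend(SeedHit(seed, off, strand) for off in offsets)
    return hits
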