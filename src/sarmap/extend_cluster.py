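"""Bidirectional seed extension and clustering into candidate alignment
locations (CALs).

Each exact seed hit is grown gap-free in both directions under a shared
mismatch budget (alternating one base left, one base right, left first);
extensions near each other on the genome and on a compatible diagonal are
clustered into a CAL, and the CALs that best cover the read move on to
gap filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .index import CODE_N, ReferenceGenome, encode_sequence
from .seeding import Read, SeedHit, reverse_complement


@dataclass(frozen=True)
class ExtendedSeed:
    """Gap-free enlargement of a seed hit; half-open spans, oriented read."""

    read_start: int
    read_end: int
    genome_start: int
    genome_end: int
    strand: str
    mismatches: int

    @property
    def diagonal(self) -> int:
        return self.genome_start - self.read_start

    @property
    def span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class CAL:
    """Candidate alignment location: a cluster of extended seeds."""

    chrom: int  # chromosome index within the genome
    strand: str
    genome_start: int
    genome_end: int
    members: list[ExtendedSeed] = field(default_factory=list)
    read_coverage: int = 0
    score: float | None = None

    @property
    def total_mismatches(self) -> int:
        return sum(m.mismatches for m in self.members)


def extend_seed(
    hit: SeedHit,
    read: Read,
    genome: ReferenceGenome,
    max_mismatches: int,
    _read_codes: np.ndarray | None = None,
) -> ExtendedSeed:
    """Extend a verified exact hit in both directions under a mismatch budget.

    The walk alternates one base leftward then one base rightward (left
    first, skipping exhausted directions).  A compared pair that differs,
    or involves an N on either side, costs one mismatch; a direction stops
    when its next comparison would exceed the budget or when the read or
    chromosome boundary is reached.  Mismatching bases accepted within the
    budget stay inside the returned span.
    """
    if _read_codes is not None:
        rc = _read_codes
    else:
        oriented = read.sequence if hit.strand == "+" else reverse_complement(read.sequence)
        rc = encode_sequence(oriented)
    tc = genome.codes
    s0, slen = hit.seed.read_offset, hit.seed.length
    g = hit.genome_offset
    cidx, _ = genome.offset_to_locus(g)
    cstart, cend = genome.chrom_bounds(cidx)

    left_cap = min(s0, g - cstart)
    right_cap = min(rc.size - (s0 + slen), cend - (g + slen))

    a = rc[s0 - left_cap : s0][::-1]
    b = tc[g - left_cap : g][::-1]
    mis_left = np.flatnonzero((a != b) | (a == CODE_N) | (b == CODE_N)) + 1
    a = rc[s0 + slen : s0 + slen + right_cap]
    b = tc[g + slen : g + slen + right_cap]
    mis_right = np.flatnonzero((a != b) | (a == CODE_N) | (b == CODE_N)) + 1

    # consume mismatch events in the order the alternating walk meets them:
    # the d-th left base is compared at tick 2d-1, the d-th right base at 2d
    count = 0
    i = j = 0
    while count < max_mismatches:
        dl = int(mis_left[i]) if i < mis_left.size else None
        dr = int(mis_right[j]) if j < mis_right.size else None
        if dl is None and dr is None:
            break
        if dr is None or (dl is not None and 2 * dl - 1 < 2 * dr):
            i += 1
        else:
            j += 1
        count += 1
    left_ext = int(mis_left[i]) - 1 if i < mis_left.size else left_cap
    right_ext = int(mis_right[j]) - 1 if j < mis_right.size else right_cap

    return ExtendedSeed(
        read_start=s0 - left_ext,
        read_end=s0 + slen + right_ext,
        genome_start=g - left_ext,
        genome_end=g + slen + right_ext,
        strand=hit.strand,
        mismatches=count,
    )


def _union_length(spans: list[tuple[int, int]]) -> int:
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(spans):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def cluster_extensions(
    extensions: list[ExtendedSeed],
    max_gap: int,
    min_cal_length: int,
    genome: ReferenceGenome,
) -> list[CAL]:
    """Group extensions of one read into CALs.

    Extensions are grouped per (chromosome, strand) and chained in genome
    order: two consecutive extensions join the same CAL when the genomic
    distance between their spans is at most ``max_gap`` and their
    diagonals differ by at most ``max_gap`` (a larger diagonal jump
    implies an indel the cluster cannot represent).  CALs whose genomic
    envelope is shorter than ``min_cal_length`` are discarded.
    """
    groups: dict[tuple[int, str], list[ExtendedSeed]] = {}
    for ext in extensions:
        cidx, _ = genome.offset_to_locus(ext.genome_start)
        groups.setdefault((cidx, ext.strand), []).append(ext)

    cals: list[CAL] = []

    def flush(cidx: int, strand: str, chain: list[ExtendedSeed]) -> None:
        start = min(e.genome_start for e in chain)
        end = max(e.genome_end for e in chain)
        if end - start < min_cal_length:
            return
        cals.append(
            CAL(
                chrom=cidx,
                strand=strand,
                genome_start=start,
                genome_end=end,
                members=list(chain),
                read_coverage=_union_length([(e.read_start, e.read_end) for e in chain]),
            )
        )

    for (cidx, strand) in sorted(groups):
        members = sorted(groups[(cidx, strand)], key=lambda e: (e.genome_start, e.genome_end))
        chain = [members[0]]
        for ext in members[1:]:
            prev = chain[-1]
            gap = ext.genome_start - prev.genome_end
            if gap <= max_gap and abs(ext.diagonal - prev.diagonal) <= max_gap:
                chain.append(ext)
            else:
                flush(cidx, strand, chain)
                chain = [ext]
        flush(cidx, strand, chain)
    return cals


def select_cals(cals: list[CAL], read: Read, max_cals: int) -> list[CAL]:
    """Keep the ``max_cals`` best CALs, ranked by read coverage.

    Ties break toward fewer total member mismatches, then the leftmost
    genome coordinate (chromosome order, then position), then the forward
    strand.
    """
    ranked = sorted(
        cals,
        key=lambda c: (
            -c.read_coverage,
            c.total_mismatches,
            c.chrom,
            c.genome_start,
            0 if c.strand == "+" else 1,
        ),
    )
    return ranked[:max_cals]
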