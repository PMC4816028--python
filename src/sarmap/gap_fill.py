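"""Mapping completion: Smith-Waterman gap filling, scoring and batching.

Selected CALs are turned into full alignments: the extended seeds become
anchored match/mismatch runs, every unaligned gap between anchors is
aligned with an affine-gap local Smith-Waterman, unreconciled read ends
are soft-clipped, and the CAL score

    score = match*matches - mismatch*mismatches
            - gap_open*gap_runs - gap_extend*gapped_bases

decides which candidate is reported.  ``run_batches`` processes reads in
fixed-size batches with a strict determinism contract: output order and
content are identical for any worker count.
"""

from __future__ import annotations

import math
import multiprocessing
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .extend_cluster import (
    CAL,
    ExtendedSeed,
    cluster_extensions,
    extend_seed,
    select_cals,
)
from .index import CODE_N, ReferenceGenome, ReferenceIndex, decode_sequence, encode_sequence
from .seeding import Read, default_num_seeds, map_seeds, reverse_complement


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring: positive match reward, penalty magnitudes.

    A gap run of length g costs gap_open + g*gap_extend.
    """

    match: float = 5.0
    mismatch: float = 4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties are magnitudes and must be >= 0")


@dataclass(frozen=True)
class SWPath:
    """Local alignment footprint: half-open spans plus M/I/D run list."""

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    ops: tuple[tuple[str, int], ...]


_DIAG, _DEL, _INS, _STOP = 1, 2, 3, 0


def smith_waterman(query: str, target: str, scheme: ScoringScheme) -> tuple[float, SWPath | None]:
    """Affine-gap local alignment of ``query`` against ``target``.

    Returns (score, path); path is None when no positive-scoring local
    alignment exists.  N never matches anything (scored as mismatch).
    Traceback ties prefer diagonal, then deletion (target-consuming), then
    insertion; the start cell is the rightmost maximal cell (largest query
    index, then largest target index).
    """
    if not query or not target:
        raise ValueError("smith_waterman requires nonempty sequences")
    q = encode_sequence(query)
    t = encode_sequence(target)
    n, m = q.size, t.size
    open_cost = scheme.gap_open + scheme.gap_extend  # first gapped base
    ext_cost = scheme.gap_extend
    neg = -math.inf

    hrow_prev = [0.0] * (m + 1)
    erow_prev = [neg] * (m + 1)
    H = [[0.0] * (m + 1)]
    ptr_h = [[_STOP] * (m + 1) for _ in range(n + 1)]
    ptr_e = [[False] * (m + 1) for _ in range(n + 1)]  # True: extend existing gap
    ptr_f = [[False] * (m + 1) for _ in range(n + 1)]
    hmat = [hrow_prev]
    emat = [erow_prev]
    fmat = [[neg] * (m + 1)]

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        hrow = [0.0] * (m + 1)
        erow = [neg] * (m + 1)
        frow = [neg] * (m + 1)
        qi = q[i - 1]
        ph = hmat[i - 1]
        pe = emat[i - 1]
        pre = ptr_e[i]
        prf = ptr_f[i]
        prh = ptr_h[i]
        fprev = neg
        for j in range(1, m + 1):
            # E: gap in target (insertion, consumes query) - vertical move
            e_open = ph[j] - open_cost
            e_ext = pe[j] - ext_cost
            if e_ext > e_open:
                e = e_ext
                pre[j] = True
            else:
                e = e_open
                pre[j] = False
            erow[j] = e
            # F: gap in query (deletion, consumes target) - horizontal move
            f_open = hrow[j - 1] - open_cost
            f_ext = fprev - ext_cost
            if f_ext > f_open:
                f = f_ext
                prf[j] = True
            else:
                f = f_open
                prf[j] = False
            frow[j] = f
            fprev = f
            tj = t[j - 1]
            sub = scheme.match if (qi == tj and qi != CODE_N) else -scheme.mismatch
            diag = ph[j - 1] + sub
            # tie preference: diagonal, then deletion, then insertion
            h = diag
            p = _DIAG
            if f > h:
                h, p = f, _DEL
            if e > h:
                h, p = e, _INS
            if h <= 0.0:
                h, p = 0.0, _STOP
            hrow[j] = h
            prh[j] = p
            if h >= best:
                best, bi, bj = h, i, j
        hmat.append(hrow)
        emat.append(erow)
        fmat.append(frow)

    if best <= 0.0:
        return 0.0, None

    # traceback
    ops_rev: list[tuple[str, int]] = []

    def push(op: str) -> None:
        if ops_rev and ops_rev[-1][0] == op:
            ops_rev[-1] = (op, ops_rev[-1][1] + 1)
        else:
            ops_rev.append((op, 1))

    i, j = bi, bj
    while i > 0 and j > 0:
        p = ptr_h[i][j]
        if p == _STOP:
            break
        if p == _DIAG:
            push("M")
            i -= 1
            j -= 1
        elif p == _DEL:
            while j > 0:
                extend = ptr_f[i][j]
                push("D")
                j -= 1
                if not extend:
                    break
        else:  # _INS
            while i > 0:
                extend = ptr_e[i][j]
                push("I")
                i -= 1
                if not extend:
                    break

    ops = tuple(reversed(ops_rev))
    return best, SWPath(q_start=i, q_end=bi, t_start=j, t_end=bj, ops=ops)


# --------------------------------------------------------------------------
# alignment assembly


@dataclass
class Alignment:
    """A completed mapping, one per read, serializable as a SAM record."""

    read_id: str
    chrom: str | None
    position: int  # 1-based leftmost mapped reference base; 0 if unmapped
    strand: str  # '+', '-' ('.' when unmapped)
    cigar: list[tuple[str, int]]
    score: float
    mapq: int
    aligned_read_fraction: float
    seq: str  # strand-oriented sequence as stored in SAM
    qual: str
    nm: int = 0
    mapped: bool = True
    chrom_idx: int = -1

    @property
    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{length}{op}" for op, length in self.cigar)

    def read_consumed(self) -> int:
        return sum(length for op, length in self.cigar if op in "MIS")

    def ref_consumed(self) -> int:
        return sum(length for op, length in self.cigar if op in "MD")


def score_alignment(
    ops: list[tuple[str, int]],
    read_codes: np.ndarray,
    ref_codes: np.ndarray,
    ref_start: int,
    scheme: ScoringScheme,
) -> tuple[float, int, int, int, int]:
    """Score a CIGAR against the sequences it aligns.

    Returns (score, matches, mismatches, gap_runs, gapped_bases); N on
    either side counts as a mismatch; soft-clips contribute nothing.
    """
    rpos, gpos = 0, ref_start
    matches = mismatches = gap_runs = gapped = 0
    for op, length in ops:
        if op == "S":
            rpos += length
        elif op == "M":
            a = read_codes[rpos : rpos + length]
            b = ref_codes[gpos : gpos + length]
            mism = int(np.count_nonzero((a != b) | (a == CODE_N) | (b == CODE_N)))
            mismatches += mism
            matches += length - mism
            rpos += length
            gpos += length
        elif op == "I":
            gap_runs += 1
            gapped += length
            rpos += length
        elif op == "D":
            gap_runs += 1
            gapped += length
            gpos += length
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    score = (
        scheme.match * matches
        - scheme.mismatch * mismatches
        - scheme.gap_open * gap_runs
        - scheme.gap_extend * gapped
    )
    return score, matches, mismatches, gap_runs, gapped


class _OpBuilder:
    def __init__(self) -> None:
        self.ops: list[tuple[str, int]] = []

    def push(self, op: str, length: int) -> None:
        if length <= 0:
            return
        if self.ops and self.ops[-1][0] == op:
            self.ops[-1] = (op, self.ops[-1][1] + length)
        else:
            self.ops.append((op, length))

    def extend(self, ops: Iterable[tuple[str, int]]) -> None:
        for op, length in ops:
            self.push(op, length)


def _prepare_anchors(members: list[ExtendedSeed], read_len: int) -> list[ExtendedSeed]:
    """Reduce CAL members to a consistent chain of gap-free anchors.

    Same-diagonal overlapping members merge; remaining members are
    admitted longest-first and trimmed so that accepted anchors are
    strictly ordered in both read and genome coordinates (a candidate
    incompatible even after trimming is dropped).
    """
    # merge members sharing a diagonal whose read spans overlap or touch
    by_diag: dict[int, list[ExtendedSeed]] = {}
    for m in members:
        by_diag.setdefault(m.diagonal, []).append(m)
    merged: list[ExtendedSeed] = []
    for diag, group in sorted(by_diag.items()):
        group.sort(key=lambda e: e.read_start)
        cur = group[0]
        for e in group[1:]:
            if e.read_start <= cur.read_end:
                if e.read_end > cur.read_end:
                    cur = ExtendedSeed(
                        cur.read_start,
                        e.read_end,
                        cur.genome_start,
                        e.genome_end,
                        cur.strand,
                        cur.mismatches + e.mismatches,
                    )
            else:
                merged.append(cur)
                cur = e
        merged.append(cur)

    accepted: list[ExtendedSeed] = []
    for cand in sorted(merged, key=lambda e: (-e.span, e.read_start, e.genome_start)):
        ok = True
        for other in accepted:
            if cand.read_start >= other.read_end and cand.genome_start >= other.genome_end:
                continue  # cleanly right of `other`
            if cand.read_end <= other.read_start and cand.genome_end <= other.genome_start:
                continue  # cleanly left of `other`
            if cand.read_start >= other.read_start:
                # overlaps from the right: trim candidate's left edge
                cut = max(
                    other.read_end - cand.read_start,
                    other.genome_end - cand.genome_start,
                )
                cand = ExtendedSeed(
                    cand.read_start + cut,
                    cand.read_end,
                    cand.genome_start + cut,
                    cand.genome_end,
                    cand.strand,
                    cand.mismatches,
                )
            else:
                cut = max(
                    cand.read_end - other.read_start,
                    cand.genome_end - other.genome_start,
                )
                cand = ExtendedSeed(
                    cand.read_start,
                    cand.read_end - cut,
                    cand.genome_start,
                    cand.genome_end - cut,
                    cand.strand,
                    cand.mismatches,
                )
            if cand.span <= 0:
                ok = False
                break
        if ok:
            # re-check full consistency after trimming against everyone
            consistent = all(
                (cand.read_start >= o.read_end and cand.genome_start >= o.genome_end)
                or (cand.read_end <= o.read_start and cand.genome_end <= o.genome_start)
                for o in accepted
            )
            if consistent:
                accepted.append(cand)
    accepted.sort(key=lambda e: e.read_start)
    return accepted


_END_GAP_MARGIN = 10  # extra reference bases beyond the gap's read length


def _bridge_to_anchor(builder: _OpBuilder, q_excess: int, t_excess: int, anchor_first: bool) -> None:
    """Account for unaligned bases between a local SW path and an anchor.

    Equal-length leftovers pair as M adjacent to the anchor; the remainder
    becomes an insertion or deletion.
    """
    paired = min(q_excess, t_excess)
    ins, dele = q_excess - paired, t_excess - paired
    if anchor_first:
        builder.push("M", paired)
        builder.push("I", ins)
        builder.push("D", dele)
    else:
        builder.push("I", ins)
        builder.push("D", dele)
        builder.push("M", paired)


def fill_gaps(
    cal: CAL,
    read: Read,
    genome: ReferenceGenome,
    scheme: ScoringScheme | None = None,
) -> Alignment:
    """Complete one CAL into a scored alignment.

    Anchors (extended seeds) become M runs; inter-anchor gaps are aligned
    by local Smith-Waterman with deterministic bridging to the anchors;
    read ends that local alignment does not reconcile are soft-clipped.
    """
    if not cal.members:
        raise ValueError("fill_gaps requires a CAL with at least one member")
    scheme = scheme or ScoringScheme()
    oriented = read.sequence if cal.strand == "+" else reverse_complement(read.sequence)
    qual = read.qualities if cal.strand == "+" else read.qualities[::-1]
    read_codes = encode_sequence(oriented)
    L = len(oriented)
    tcodes = genome.codes
    cstart, cend = genome.chrom_bounds(cal.chrom)

    anchors = _prepare_anchors(cal.members, L)
    if not anchors:
        raise ValueError("no consistent anchors in CAL")

    first, last = anchors[0], anchors[-1]

    # --- leading block (before the first anchor)
    lead = _OpBuilder()
    lead_len = first.read_start
    if lead_len:
        rseg = oriented[:lead_len]
        ref_lo = max(cstart, first.genome_start - (lead_len + _END_GAP_MARGIN))
        gseg = decode_sequence(tcodes[ref_lo : first.genome_start])
        handled = False
        if gseg:
            _, path = smith_waterman(rseg, gseg, scheme)
            if path is not None:
                lead.push("S", path.q_start)
                lead.extend(path.ops)
                _bridge_to_anchor(
                    lead, lead_len - path.q_end, len(gseg) - path.t_end, anchor_first=False
                )
                handled = True
        if not handled:
            lead.push("S", lead_len)

    # --- middle: anchors and inter-anchor gaps
    mid = _OpBuilder()
    mid.push("M", first.span)
    for prev, cur in zip(anchors, anchors[1:]):
        rseg = oriented[prev.read_end : cur.read_start]
        gseg = decode_sequence(tcodes[prev.genome_end : cur.genome_start])
        if not rseg and not gseg:
            pass
        elif not rseg:
            mid.push("D", len(gseg))
        elif not gseg:
            mid.push("I", len(rseg))
        else:
            _, path = smith_waterman(rseg, gseg, scheme)
            if path is not None:
                _bridge_to_anchor(mid, path.q_start, path.t_start, anchor_first=True)
                mid.extend(path.ops)
                _bridge_to_anchor(
                    mid, len(rseg) - path.q_end, len(gseg) - path.t_end, anchor_first=False
                )
            else:
                _bridge_to_anchor(mid, len(rseg), len(gseg), anchor_first=True)
        mid.push("M", cur.span)

    # --- trailing block (after the last anchor)
    trail = _OpBuilder()
    tail_len = L - last.read_end
    if tail_len:
        rseg = oriented[last.read_end :]
        ref_hi = min(cend, last.genome_end + tail_len + _END_GAP_MARGIN)
        gseg = decode_sequence(tcodes[last.genome_end : ref_hi])
        handled = False
        if gseg:
            _, path = smith_waterman(rseg, gseg, scheme)
            if path is not None:
                _bridge_to_anchor(trail, path.q_start, path.t_start, anchor_first=True)
                trail.extend(path.ops)
                trail.push("S", tail_len - path.q_end)
                handled = True
        if not handled:
            trail.push("S", tail_len)

    lead_ref = sum(length for op, length in lead.ops if op in "MD")
    genome_pos = first.genome_start - lead_ref

    builder = _OpBuilder()
    builder.extend(lead.ops)
    builder.extend(mid.ops)
    builder.extend(trail.ops)
    ops = builder.ops

    score, matches, mismatches, gap_runs, gapped = score_alignment(
        ops, read_codes, tcodes, genome_pos, scheme
    )
    aligned = sum(length for op, length in ops if op == "M")
    nm = mismatches + gapped

    return Alignment(
        read_id=read.id,
        chrom=genome.chrom_names[cal.chrom],
        position=genome_pos - cstart + 1,
        strand=cal.strand,
        cigar=ops,
        score=score,
        mapq=0,
        aligned_read_fraction=aligned / L,
        seq=oriented,
        qual=qual,
        nm=nm,
        mapped=True,
        chrom_idx=cal.chrom,
    )


def unmapped_alignment(read: Read) -> Alignment:
    return Alignment(
        read_id=read.id,
        chrom=None,
        position=0,
        strand=".",
        cigar=[],
        score=0.0,
        mapq=0,
        aligned_read_fraction=0.0,
        seq=read.sequence,
        qual=read.qualities,
        nm=0,
        mapped=False,
        chrom_idx=-1,
    )


def finalize_read(alignments: list[Alignment], read: Read) -> Alignment:
    """Pick the reported mapping and assign its mapping quality.

    The highest CAL score wins (ties: chromosome order, then coordinate,
    then forward strand).  MAPQ is 60 for a unique candidate, 0 when the
    best and second-best scores tie, otherwise
    min(60, round((best - second)/best * 60)).
    """
    if not alignments:
        return unmapped_alignment(read)
    ranked = sorted(
        alignments,
        key=lambda a: (-a.score, a.chrom_idx, a.position, 0 if a.strand == "+" else 1),
    )
    best = ranked[0]
    if len(ranked) == 1:
        best.mapq = 60
    else:
        second = ranked[1].score
        if best.score <= second or best.score <= 0:
            best.mapq = 0
        else:
            best.mapq = min(60, round((best.score - second) / best.score * 60))
    return best


# --------------------------------------------------------------------------
# full per-read pipeline and batch processing


@dataclass
class MapParams:
    """Tunable mapping parameters; None means a per-read default.

    seed_length defaults to the index prefix length; num_seeds to
    max(5, floor(L/s)); max_mismatches to ceil(0.04*L); max_gap to 2*L;
    min_cal_length to 0.25*L.
    """

    seed_length: int | None = None
    num_seeds: int | None = None
    max_hits_per_seed: int = 100
    max_mismatches: int | None = None
    max_gap: int | None = None
    min_cal_length: int | None = None
    max_cals: int = 5
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    batch_size: int = 256


def map_read(read: Read, index: ReferenceIndex, params: MapParams | None = None) -> Alignment:
    """Seed, extend, cluster, gap-fill and finalize one read."""
    params = params or MapParams()
    genome = index.genome
    L = len(read)
    s = params.seed_length if params.seed_length is not None else index.ptable.k
    n = params.num_seeds if params.num_seeds is not None else default_num_seeds(L, s)
    budget = (
        params.max_mismatches
        if params.max_mismatches is not None
        else math.ceil(0.04 * L)
    )
    max_gap = params.max_gap if params.max_gap is not None else 2 * L
    min_cal = params.min_cal_length if params.min_cal_length is not None else int(0.25 * L)

    hits = map_seeds(read, index, s, n, params.max_hits_per_seed)
    if not hits:
        return unmapped_alignment(read)

    oriented_codes = {
        "+": encode_sequence(read.sequence),
        "-": encode_sequence(reverse_complement(read.sequence)),
    }
    extensions: list[ExtendedSeed] = []
    seen: set[tuple[str, int, int, int]] = set()
    for hit in hits:
        ext = extend_seed(hit, read, genome, budget, _read_codes=oriented_codes[hit.strand])
        key = (ext.strand, ext.read_start, ext.read_end, ext.genome_start)
        if key not in seen:
            seen.add(key)
            extensions.append(ext)

    cals = cluster_extensions(extensions, max_gap, min_cal, genome)
    cals = select_cals(cals, read, params.max_cals)
    alignments = [fill_gaps(cal, read, genome, params.scheme) for cal in cals]
    return finalize_read(alignments, read)


_WORKER_STATE: dict = {}


def _init_worker(index: ReferenceIndex, params: MapParams) -> None:
    _WORKER_STATE["index"] = index
    _WORKER_STATE["params"] = params


def _map_batch(batch: list[Read]) -> list[Alignment]:
    index = _WORKER_STATE["index"]
    params = _WORKER_STATE["params"]
    return [map_read(read, index, params) for read in batch]


def _batched(reads: Iterable[Read], size: int) -> Iterator[list[Read]]:
    batch: list[Read] = []
    for read in reads:
        batch.append(read)
        if len(batch) >= size:
            yield batch
            batch = []
    if batch:
        yield batch


def run_batches(
    reads: Iterable[Read],
    index: ReferenceIndex,
    params: MapParams | None = None,
    workers: int = 1,
) -> Iterator[Alignment]:
    """Map a read stream in fixed-size batches.

    Output order equals input order and results are identical for any
    ``workers`` value; with workers > 1 batches are distributed over a
    process pool (falling back to sequential execution where process
    forking is unavailable).
    """
    params = params or MapParams()
    if workers < 1:
        raise ValueError("workers must be >= 1")
    batches = _batched(reads, params.batch_size)
    if workers == 1:
        _init_worker(index, params)
        for batch in batches:
            yield from _map_batch(batch)
        return
    try:
        ctx = multiprocessing.get_context("fork")
    except ValueError:
        _init_worker(index, params)
        for batch in batches:
            yield from _map_batch(batch)
        return
    with ctx.Pool(workers, initializer=_init_worker, initargs=(index, params)) as pool:
        for result in pool.imap(_map_batch, batches):
            yield from result
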