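"""Suffix-array reference index with a k-mer prefix lookup table.

The reference genome is stored as a single concatenated string in which a
sentinel character (``$``, lexicographically smaller than any nucleotide)
terminates every chromosome, so exact matches can never span a chromosome
boundary.  On top of the concatenation the index keeps

* an **uncompressed suffix array** over every non-sentinel start position,
  ordered by lexicographic rank of the suffix beginning there, and
* a **prefix table**: a sparse (compressed-row) mapping from every N-free
  k-mer that actually occurs in the genome to the half-open interval
  ``[lo, hi)`` of suffix-array ranks whose suffixes begin with it.  Only
  occurring prefixes are materialized, so memory stays proportional to the
  genome rather than to ``4**k``.

Exact pattern search first narrows to the prefix-table interval of the
pattern's first ``k`` bases (one hash-free sorted-array lookup) and
finishes with binary search inside that interval; patterns shorter than
``k`` fall back to plain binary search over the whole suffix array.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

SENTINEL = "$"
_ALPHABET = "$ACGTN"
CODE_SENTINEL, CODE_A, CODE_C, CODE_G, CODE_T, CODE_N = range(6)

_INDEX_FORMAT_VERSION = 1

# byte -> code lookup; anything that is not A/C/G/T/$ codes as N
_ENCODE_LUT = np.full(256, CODE_N, dtype=np.uint8)
for _i, _ch in enumerate(_ALPHABET):
    _ENCODE_LUT[ord(_ch)] = _i
    _ENCODE_LUT[ord(_ch.lower())] = _i
_DECODE_LUT = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)

# uppercase + normalize: every byte outside {A,C,G,T} becomes N
_NORM_TABLE = bytes(
    b if chr(b) in "ACGT" else ord("N") for b in range(256)
)


class FastaError(ValueError):
    """Raised for empty, malformed or zero-length FASTA input."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes ($=0, A=1 .. T=4, N=5)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode("ascii")


@dataclass
class ReferenceGenome:
    """Concatenated reference with per-chromosome bookkeeping.

    ``sequence`` holds every chromosome in file order, each terminated by
    one sentinel character, so ``chrom_offsets[i] + chrom_lengths[i] <
    chrom_offsets[i+1]`` and every non-sentinel offset maps to exactly one
    (chromosome, local position) pair.
    """

    sequence: str
    chrom_names: list[str]
    chrom_offsets: list[int]
    chrom_lengths: list[int]

    def __post_init__(self) -> None:
        self._codes: np.ndarray | None = None
        self._offsets_arr = np.asarray(self.chrom_offsets, dtype=np.int64)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode_sequence(self.sequence)
        return self._codes

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def offset_to_locus(self, offset: int) -> tuple[int, int]:
        """Map a concatenation offset to (chromosome index, 0-based local)."""
        idx = int(np.searchsorted(self._offsets_arr, offset, side="right")) - 1
        local = offset - self.chrom_offsets[idx]
        if not 0 <= local < self.chrom_lengths[idx]:
            raise ValueError(f"offset {offset} falls on a sentinel position")
        return idx, local

    def chrom_bounds(self, chrom_idx: int) -> tuple[int, int]:
        """Half-open concatenation interval occupied by a chromosome."""
        start = self.chrom_offsets[chrom_idx]
        return start, start + self.chrom_lengths[chrom_idx]

    def fetch(self, start: int, end: int) -> str:
        return self.sequence[start:end]


@dataclass
class SuffixArray:
    """Start offsets of all indexed suffixes in lexicographic order."""

    positions: np.ndarray  # int64, excludes sentinel start positions

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class PrefixTable:
    """Sparse k-mer -> suffix-array interval map (compressed row storage).

    ``keys`` holds the 2-bit packed codes of every distinct N-free k-mer
    occurring in the genome, sorted ascending (which coincides with
    lexicographic order), and ``lo``/``hi`` the matching half-open
    suffix-array rank intervals.
    """

    k: int
    keys: np.ndarray  # uint64, sorted
    lo: np.ndarray    # int64
    hi: np.ndarray    # int64

    def __len__(self) -> int:
        return int(self.keys.size)

    def lookup(self, key: int) -> tuple[int, int] | None:
        i = int(np.searchsorted(self.keys, np.uint64(key)))
        if i >= self.keys.size or int(self.keys[i]) != key:
            return None
        return int(self.lo[i]), int(self.hi[i])


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_reference(fasta_path) -> ReferenceGenome:
    """Read a (possibly gzipped) multi-record FASTA into a ReferenceGenome.

    Sequences are uppercased and any character outside {A,C,G,T} becomes N.
    Raises :class:`FastaError` on empty files, empty headers or zero-length
    records.
    """
    names: list[str] = []
    seqs: list[str] = []
    with _open_maybe_gzip(fasta_path) as handle:
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0] if title.strip() else ""
            if not name:
                raise FastaError(f"{fasta_path}: record {len(names) + 1} has an empty header")
            if not seq:
                raise FastaError(f"{fasta_path}: sequence {name!r} has zero length")
            names.append(name)
            seqs.append(seq.upper().encode("ascii").translate(_NORM_TABLE).decode("ascii"))
    if not names:
        raise FastaError(f"{fasta_path}: no FASTA records found")

    offsets, lengths = [], []
    cursor = 0
    for s in seqs:
        offsets.append(cursor)
        lengths.append(len(s))
        cursor += len(s) + 1  # sentinel after every chromosome
    sequence = SENTINEL.join(seqs) + SENTINEL
    return ReferenceGenome(sequence, names, offsets, lengths)


def _suffix_sort(codes: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix sort over an integer text.

    Returns the permutation of 0..n-1 ordering all suffixes
    lexicographically (a suffix that is a proper prefix of another sorts
    first, which the out-of-range rank -1 guarantees).
    """
    n = codes.size
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes.astype(np.int64)
    step = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - step] = rank[step:]
        order = np.lexsort((key2, rank))
        changed = np.empty(n, dtype=bool)
        changed[0] = True
        changed[1:] = (rank[order[1:]] != rank[order[:-1]]) | (
            key2[order[1:]] != key2[order[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:  # all ranks distinct: fully sorted
            return order.astype(np.int64)
        step *= 2


def build_suffix_array(genome: ReferenceGenome) -> SuffixArray:
    """Sort all suffixes of the concatenated genome.

    Sentinel start positions are excluded from the result: no seed may
    begin on a chromosome separator.
    """
    codes = genome.codes
    if codes.size == 0:
        raise ValueError("cannot index an empty genome")
    order = _suffix_sort(codes)
    keep = codes[order] != CODE_SENTINEL
    return SuffixArray(positions=order[keep])


def build_prefix_table(sa: SuffixArray, genome: ReferenceGenome, k: int) -> PrefixTable:
    """Group suffix-array ranks by their first k bases.

    Suffixes whose first k characters contain an N or run into a sentinel
    (i.e. are shorter than k within their chromosome) receive no entry;
    they remain reachable through plain binary search only.
    """
    if k < 1:
        raise ValueError("prefix length k must be >= 1")
    if k > 31:
        raise ValueError("prefix length k must be <= 31 (2-bit packed uint64 keys)")
    codes = genome.codes
    n = codes.size
    if n < k:
        empty = np.empty(0, dtype=np.int64)
        return PrefixTable(k=k, keys=np.empty(0, dtype=np.uint64), lo=empty, hi=empty.copy())
    is_base = (codes >= CODE_A) & (codes <= CODE_T)
    cum = np.concatenate([[0], np.cumsum(is_base, dtype=np.int64)])
    eligible = np.zeros(n, dtype=bool)
    if n >= k:
        starts = np.arange(n - k + 1)
        eligible[: n - k + 1] = (cum[starts + k] - cum[starts]) == k

    # 2-bit pack the k-mer starting at every position (garbage where not eligible)
    two_bit = np.where(is_base, codes.astype(np.uint64) - 1, np.uint64(0))
    keys_all = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        shifted = np.zeros(n, dtype=np.uint64)
        shifted[: n - i] = two_bit[i:]
        keys_all = (keys_all << np.uint64(2)) | shifted

    positions = sa.positions
    ranks = np.flatnonzero(eligible[positions])
    if ranks.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return PrefixTable(k=k, keys=np.empty(0, dtype=np.uint64), lo=empty, hi=empty.copy())

    kv = keys_all[positions[ranks]]
    change = np.empty(ranks.size, dtype=bool)
    change[0] = True
    change[1:] = kv[1:] != kv[:-1]
    run_starts = np.flatnonzero(change)
    run_ends = np.append(run_starts[1:], ranks.size) - 1
    keys = kv[run_starts]
    lo = ranks[run_starts].astype(np.int64)
    hi = (ranks[run_ends] + 1).astype(np.int64)
    # suffixes sharing the same first-k characters are contiguous in the SA
    if not np.all(hi - lo == run_ends - run_starts + 1):
        raise AssertionError("prefix-table intervals are not contiguous in the suffix array")
    return PrefixTable(k=k, keys=keys, lo=lo, hi=hi)


@dataclass
class ReferenceIndex:
    """Genome + suffix array + prefix table, built together."""

    genome: ReferenceGenome
    sa: SuffixArray
    ptable: PrefixTable
    build_params: dict = field(default_factory=dict)

    @classmethod
    def build(cls, genome: ReferenceGenome, k: int = 18) -> "ReferenceIndex":
        sa = build_suffix_array(genome)
        ptable = build_prefix_table(sa, genome, k)
        return cls(genome=genome, sa=sa, ptable=ptable, build_params={"k": k})

    # ---- persistence: versioned raw arrays + JSON metadata, byte-stable ----

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.save(outdir / "genome_codes.npy", self.genome.codes)
        np.save(outdir / "sa.npy", self.sa.positions)
        np.save(outdir / "pt_keys.npy", self.ptable.keys)
        np.save(outdir / "pt_lo.npy", self.ptable.lo)
        np.save(outdir / "pt_hi.npy", self.ptable.hi)
        meta = {
            "format_version": _INDEX_FORMAT_VERSION,
            "k": self.ptable.k,
            "chrom_names": self.genome.chrom_names,
            "chrom_offsets": self.genome.chrom_offsets,
            "chrom_lengths": self.genome.chrom_lengths,
        }
        with open(outdir / "meta.json", "w") as fh:
            json.dump(meta, fh, sort_keys=True, indent=0)
        return outdir

    @classmethod
    def load(cls, indir) -> "ReferenceIndex":
        indir = Path(indir)
        with open(indir / "meta.json") as fh:
            meta = json.load(fh)
        if meta.get("format_version") != _INDEX_FORMAT_VERSION:
            raise ValueError(f"unsupported index format version in {indir}")
        codes = np.load(indir / "genome_codes.npy")
        genome = ReferenceGenome(
            sequence=decode_sequence(codes),
            chrom_names=list(meta["chrom_names"]),
            chrom_offsets=list(meta["chrom_offsets"]),
            chrom_lengths=list(meta["chrom_lengths"]),
        )
        genome._codes = codes
        sa = SuffixArray(positions=np.load(indir / "sa.npy"))
        ptable = PrefixTable(
            k=int(meta["k"]),
            keys=np.load(indir / "pt_keys.npy"),
            lo=np.load(indir / "pt_lo.npy"),
            hi=np.load(indir / "pt_hi.npy"),
        )
        return cls(genome=genome, sa=sa, ptable=ptable, build_params={"k": int(meta["k"])})


def _compare_suffix(codes: np.ndarray, pos: int, pattern: np.ndarray) -> int:
    """Compare suffix at ``pos`` (truncated to len(pattern)) with pattern.

    Returns -1/0/+1; 0 means the suffix *starts with* the pattern.
    """
    m = pattern.size
    end = min(pos + m, codes.size)
    window = codes[pos:end]
    sub = pattern[: window.size]
    diff = np.flatnonzero(window != sub)
    if diff.size:
        i = diff[0]
        return -1 if window[i] < sub[i] else 1
    if window.size < m:
        return -1  # suffix ran out: sorts before the pattern
    return 0


def _lower_bound(codes, sa_positions, lo, hi, pattern):
    while lo < hi:
        mid = (lo + hi) // 2
        if _compare_suffix(codes, int(sa_positions[mid]), pattern) < 0:
            lo = mid + 1
        else:
            hi = mid
    return lo


def _upper_bound(codes, sa_positions, lo, hi, pattern):
    while lo < hi:
        mid = (lo + hi) // 2
        if _compare_suffix(codes, int(sa_positions[mid]), pattern) <= 0:
            lo = mid + 1
        else:
            hi = mid
    return lo


def sa_search(pattern: str, index: ReferenceIndex) -> list[int]:
    """Return every concatenation offset where ``pattern`` occurs, ascending.

    Patterns containing N (or any non-ACGT character) return no hits: only
    unambiguous nucleotide strings are indexed.  Matches never span a
    sentinel because the sentinel code never equals a nucleotide code.
    """
    if len(pattern) == 0:
        raise ValueError("empty search pattern")
    pat = encode_sequence(pattern)
    if np.any((pat < CODE_A) | (pat > CODE_T)):
        return []
    codes = index.genome.codes
    positions = index.sa.positions
    k = index.ptable.k
    m = pat.size

    if m >= k:
        key = 0
        for c in pat[:k]:
            key = (key << 2) | (int(c) - 1)
        interval = index.ptable.lookup(key)
        if interval is None:
            return []
        lo, hi = interval
        if m == k:
            return sorted(int(p) for p in positions[lo:hi])
    else:
        lo, hi = 0, positions.size

    lo2 = _lower_bound(codes, positions, lo, hi, pat)
    hi2 = _upper_bound(codes, positions, lo2, hi, pat)
    return sorted(int(p) for p in positions[lo2:hi2])
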