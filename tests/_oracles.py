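"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as directly as possible (naive sorts, sliding
windows, full dynamic-programming matrices, literal base-by-base walks)
and shares no code with the package internals it checks.
"""

from __future__ import annotations


def naive_suffix_array(text: str, skip_chars: str = "$") -> list[int]:
    """Sort all suffix start positions lexicographically by brute force."""
    positions = [i for i in range(len(text)) if text[i] not in skip_chars]
    return sorted(positions, key=lambda i: text[i:])


def naive_find_all(text: str, pattern: str) -> list[int]:
    """Every occurrence of pattern in text by sliding-window comparison."""
    m = len(pattern)
    return [i for i in range(len(text) - m + 1) if text[i : i + m] == pattern]


def naive_kmer_intervals(text: str, sa: list[int], k: int) -> dict[str, tuple[int, int]]:
    """Map each occurring N-free k-mer to its suffix-array rank interval."""
    intervals: dict[str, tuple[int, int]] = {}
    for rank, pos in enumerate(sa):
        kmer = text[pos : pos + k]
        if len(kmer) < k or any(c not in "ACGT" for c in kmer):
            continue
        if kmer in intervals:
            lo, hi = intervals[kmer]
            intervals[kmer] = (min(lo, rank), max(hi, rank + 1))
        else:
            intervals[kmer] = (rank, rank + 1)
    return intervals


def sw_score_oracle(query: str, target: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Best affine-gap local alignment score by a full three-matrix DP.

    A gap of length g costs gap_open + g*gap_extend; N matches nothing.
    """
    n, m = len(query), len(target)
    neg = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            same = query[i - 1] == target[j - 1] and query[i - 1] != "N"
            sub = match if same else -mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def extension_walk_oracle(read: str, genome: str, read_offset: int, seed_len: int,
                          genome_offset: int, budget: int,
                          chrom_start: int, chrom_end: int) -> tuple[int, int, int]:
    """Literal alternating one-base walk (left first) under a mismatch budget.

    Returns (left_extension, right_extension, mismatches_accepted).
    """
    left = right = count = 0
    left_cap = min(read_offset, genome_offset - chrom_start)
    right_cap = min(len(read) - (read_offset + seed_len),
                    chrom_end - (genome_offset + seed_len))
    left_active = left_cap > 0
    right_active = right_cap > 0
    while left_active or right_active:
        if left_active:
            a = read[read_offset - left - 1]
            b = genome[genome_offset - left - 1]
            if a != b or a == "N" or b == "N":
                if count >= budget:
                    left_active = False
                else:
                    count += 1
                    left += 1
            else:
                left += 1
            if left >= left_cap:
                left_active = False
        if right_active:
            a = read[read_offset + seed_len + right]
            b = genome[genome_offset + seed_len + right]
            if a != b or a == "N" or b == "N":
                if count >= budget:
                    right_active = False
                else:
                    count += 1
                    right += 1
            else:
                right += 1
            if right >= right_cap:
                right_active = False
    return left, right, count
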