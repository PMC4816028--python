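"""Synthetic genomes, dwgsim-style reads with encoded truth, and evaluation.

The simulator draws reads from uniform random positions and strands,
applies per-base mutations (a fraction of which are indels with
geometric lengths), then per-base sequencing errors, and encodes the
true origin in the read name so the evaluator can score a SAM file with
the positional (chromosome + strand + position within a tolerance) or
coverage-augmented correctness rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .index import ReferenceGenome, load_reference

_BASES = "ACGT"
_Q_GOOD = "I"  # Q40 for correct bases
_Q_ERR = "+"   # Q10 at simulated sequencing-error positions


@dataclass
class SimParams:
    """Read-simulation settings (dwgsim-style).

    mut_rate: per-base mutation probability; indel_frac: fraction of
    mutations that are indels (insertion/deletion equiprobable);
    indel_ext: probability an indel run extends by one more base
    (geometric lengths with mean 1/(1-indel_ext)); err_rate: per-base
    sequencer substitution error probability; max_n: reads with more N
    bases are redrawn.
    """

    mut_rate: float = 0.001
    indel_frac: float = 0.1
    indel_ext: float = 0.30
    err_rate: float = 0.020
    max_n: int = 2
    read_len: int = 100
    n_reads: int = 10000
    rng_seed: int = 1

    def __post_init__(self) -> None:
        for name in ("mut_rate", "indel_frac", "indel_ext", "err_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} is not a probability")
        if self.read_len < 1 or self.n_reads < 0:
            raise ValueError("read_len must be >= 1 and n_reads >= 0")


@dataclass(frozen=True)
class ReadTruth:
    """Ground-truth origin of a simulated read, encoded in its name."""

    read_id: str
    chrom: str
    strand: str  # '+' or '-'
    true_start: int  # 1-based leftmost origin on the reference


@dataclass
class SimStats:
    """Aggregate mutation bookkeeping across a simulated dataset."""

    n_reads: int = 0
    n_substitutions: int = 0
    n_indels: int = 0
    indel_bases: int = 0


@dataclass
class EvalReport:
    n_reads: int
    pct_correct: float
    pct_incorrect: float
    pct_unmapped: float
    rule: str


def make_truth_name(chrom: str, true_start: int, strand: str, serial: int) -> str:
    """Truth grammar: ``{chrom}_{start1based}_{0|1}_{serial}`` (0=forward)."""
    return f"{chrom}_{true_start}_{0 if strand == '+' else 1}_{serial}"


def parse_truth_name(read_id: str) -> ReadTruth:
    try:
        chrom, start, strand01, _serial = read_id.rsplit("_", 3)
        return ReadTruth(
            read_id=read_id,
            chrom=chrom,
            strand="+" if int(strand01) == 0 else "-",
            true_start=int(start),
        )
    except ValueError as exc:
        raise ValueError(f"read id {read_id!r} does not follow the truth grammar") from exc


def simulate_genome(length: int, n_chroms: int, rng_seed: int, out_fasta) -> Path:
    """Write an i.i.d. uniform A/C/G/T genome split into ``n_chroms`` records."""
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    if n_chroms < 1 or n_chroms > length:
        raise ValueError("n_chroms must be in [1, length]")
    rng = np.random.default_rng(rng_seed)
    bases = rng.integers(0, 4, size=length)
    seq = np.frombuffer(_BASES.encode(), dtype=np.uint8)[bases].tobytes().decode()
    base_len, extra = divmod(length, n_chroms)
    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as fh:
        cursor = 0
        for i in range(n_chroms):
            clen = base_len + (1 if i < extra else 0)
            fh.write(f">chr{i + 1}\n")
            chunk = seq[cursor : cursor + clen]
            for j in range(0, clen, 70):
                fh.write(chunk[j : j + 70] + "\n")
            cursor += clen
    return out_fasta


def _mutate_template(window: np.ndarray, params: SimParams, rng) -> tuple[np.ndarray | None, int, int, int]:
    """Apply mutations to a 0..3-coded template; returns read_len bases.

    Returns (read, n_substitutions, n_indels, indel_bases); read is None
    when the template is exhausted before read_len bases are produced.
    """
    read_len = params.read_len
    u = rng.random(window.size)
    mut_positions = np.flatnonzero(u < params.mut_rate)
    pieces: list[np.ndarray] = []
    produced = 0
    tpos = 0
    n_sub = n_ind = ind_bases = 0
    for mp in mut_positions:
        mp = int(mp)
        if mp < tpos:
            continue  # swallowed by a previous deletion
        if produced + (mp - tpos) >= read_len:
            break
        pieces.append(window[tpos:mp])
        produced += mp - tpos
        if rng.random() < params.indel_frac:
            run = 1
            while rng.random() < params.indel_ext:
                run += 1
            n_ind += 1
            ind_bases += run
            if rng.random() < 0.5:  # insertion before the current base
                ins = rng.integers(0, 4, size=run)
                pieces.append(ins)
                produced += run
                tpos = mp
            else:  # deletion of `run` template bases
                tpos = mp + run
        else:
            n_sub += 1
            base = (int(window[mp]) + int(rng.integers(1, 4))) % 4
            pieces.append(np.array([base], dtype=window.dtype))
            produced += 1
            tpos = mp + 1
    pieces.append(window[tpos:])
    read = np.concatenate(pieces)[:read_len] if pieces else window[:read_len]
    if read.size < read_len:
        return None, n_sub, n_ind, ind_bases
    return read.astype(np.int64), n_sub, n_ind, ind_bases


def simulate_reads(
    genome: ReferenceGenome,
    params: SimParams,
    out_fastq,
    truth_tsv=None,
) -> tuple[list[ReadTruth], SimStats]:
    """Simulate single-end reads and write FASTQ (+ optional truth TSV).

    Each read is drawn from a uniform random position and strand; mutations
    are applied first (substitutions or geometric-length indels), then
    per-base sequencing errors (substitutions marked with low quality).
    Reads with more than ``max_n`` N bases are redrawn.  Truth is encoded
    in the read name (see :func:`make_truth_name`).
    """
    rng = np.random.default_rng(params.rng_seed)
    read_len = params.read_len
    slack = max(50, int(0.02 * read_len))
    usable = np.array(
        [max(0, clen - read_len + 1) for clen in genome.chrom_lengths], dtype=np.float64
    )
    if usable.sum() == 0:
        raise ValueError("read_len exceeds every chromosome length")
    weights = usable / usable.sum()
    codes = genome.codes

    truths: list[ReadTruth] = []
    stats = SimStats()
    out_fastq = Path(out_fastq)
    with open(out_fastq, "w") as fq:
        for serial in range(params.n_reads):
            while True:
                cidx = int(rng.choice(len(weights), p=weights))
                cstart, _ = genome.chrom_bounds(cidx)
                clen = genome.chrom_lengths[cidx]
                start = int(rng.integers(0, clen - read_len + 1))
                lo = cstart + start
                hi = min(cstart + clen, lo + read_len + slack)
                window = codes[lo:hi].astype(np.int64) - 1  # 0..3
                read, n_sub, n_ind, ind_bases = _mutate_template(window, params, rng)
                if read is None:
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    read = 3 - read[::-1]
                err_mask = rng.random(read_len) < params.err_rate
                err_pos = np.flatnonzero(err_mask)
                if err_pos.size:
                    shift = rng.integers(1, 4, size=err_pos.size)
                    read[err_pos] = (read[err_pos] + shift) % 4
                seq = "".join(_BASES[b] for b in read)
                if seq.count("N") > params.max_n:
                    continue
                break
            stats.n_reads += 1
            stats.n_substitutions += n_sub
            stats.n_indels += n_ind
            stats.indel_bases += ind_bases
            qual = np.full(read_len, ord(_Q_GOOD), dtype=np.uint8)
            qual[err_pos] = ord(_Q_ERR)
            name = make_truth_name(genome.chrom_names[cidx], start + 1, strand, serial)
            truths.append(
                ReadTruth(read_id=name, chrom=genome.chrom_names[cidx], strand=strand, true_start=start + 1)
            )
            fq.write(f"@{name}\n{seq}\n+\n{qual.tobytes().decode()}\n")

    if truth_tsv is not None:
        with open(truth_tsv, "w") as fh:
            fh.write("read_id\tchrom\ttrue_start\tstrand\n")
            for t in truths:
                fh.write(f"{t.read_id}\t{t.chrom}\t{t.true_start}\t{t.strand}\n")
    return truths, stats


def load_truth_tsv(path) -> dict[str, ReadTruth]:
    truth: dict[str, ReadTruth] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing truth TSV header")
        for line in fh:
            read_id, chrom, start, strand = line.rstrip("\n").split("\t")
            truth[read_id] = ReadTruth(read_id, chrom, strand, int(start))
    return truth


def evaluate(
    sam_path,
    truth: dict[str, ReadTruth] | None = None,
    rule: str = "position_pm5",
    tolerance: int = 5,
    min_coverage: float = 0.8,
) -> EvalReport:
    """Score a SAM file against simulated ground truth.

    ``position_pm5``: a mapped read is correct iff chromosome and strand
    match and |POS - true_start| <= tolerance.  ``coverage80``
    additionally requires that at least ``min_coverage`` of the read's
    bases are aligned (M operations).  Unmapped reads are counted
    separately; percentages are rounded to 2 decimals.
    """
    if rule not in ("position_pm5", "coverage80"):
        raise ValueError(f"unknown evaluation rule {rule!r}")
    n_reads = correct = incorrect = unmapped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            read_id = rec.query_name
            if truth is not None:
                t = truth.get(read_id)
                if t is None:
                    raise ValueError(f"read id {read_id!r} missing from the truth table")
            else:
                t = parse_truth_name(read_id)
            n_reads += 1
            if rec.is_unmapped:
                unmapped += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            ok = (
                rec.reference_name == t.chrom
                and strand == t.strand
                and abs(rec.reference_start + 1 - t.true_start) <= tolerance
            )
            if ok and rule == "coverage80":
                read_length = rec.query_length or rec.infer_read_length()
                m_bases = sum(ln for op, ln in rec.cigartuples if op == 0)
                ok = read_length > 0 and m_bases / read_length >= min_coverage
            if ok:
                correct += 1
            else:
                incorrect += 1
    if n_reads == 0:
        return EvalReport(0, 0.0, 0.0, 0.0, rule)
    return EvalReport(
        n_reads=n_reads,
        pct_correct=round(100.0 * correct / n_reads, 2),
        pct_incorrect=round(100.0 * incorrect / n_reads, 2),
        pct_unmapped=round(100.0 * unmapped / n_reads, 2),
        rule=rule,
    )


__all__ = [
    "SimParams",
    "ReadTruth",
    "SimStats",
    "EvalReport",
    "simulate_genome",
    "simulate_reads",
    "evaluate",
    "make_truth_name",
    "parse_truth_name",
    "load_truth_tsv",
    "load_reference",
]
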