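"""FASTQ input (plain or gzip, several files per run) and SAM/BAM output."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .gap_fill import Alignment
from .index import ReferenceGenome
from .seeding import Read


class FastqFormatError(ValueError):
    """Raised for truncated records or sequence/quality length mismatches."""


class SamConsistencyError(ValueError):
    """Raised when an alignment violates SAM conservation rules."""


def _open_maybe_gzip(path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(paths: Iterable) -> Iterator[Read]:
    """Stream reads from one or more FASTQ files, file by file, in order.

    Gzipped input is detected by magic bytes.  Malformed records raise
    :class:`FastqFormatError` carrying the file and record number.
    """
    for path in paths:
        record_no = 0
        with _open_maybe_gzip(path) as handle:
            iterator = FastqGeneralIterator(handle)
            while True:
                try:
                    title, seq, qual = next(iterator)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise FastqFormatError(
                        f"{path}: record {record_no + 1}: {exc}"
                    ) from exc
                record_no += 1
                yield Read(title.split()[0], seq.upper(), qual)


def _sam_header_lines(genome: ReferenceGenome, command_line: str | None = None) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for name, length in zip(genome.chrom_names, genome.chrom_lengths):
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    pg = f"@PG\tID:sarmap\tPN:sarmap\tVN:{__version__}"
    if command_line:
        pg += f"\tCL:{command_line}"
    lines.append(pg)
    return lines


def _check_record(aln: Alignment, genome: ReferenceGenome) -> None:
    if not aln.mapped:
        return
    if aln.read_consumed() != len(aln.seq):
        raise SamConsistencyError(
            f"{aln.read_id}: CIGAR consumes {aln.read_consumed()} read bases, "
            f"sequence has {len(aln.seq)}"
        )
    try:
        cidx = genome.chrom_names.index(aln.chrom)
    except ValueError:
        raise SamConsistencyError(f"{aln.read_id}: unknown chromosome {aln.chrom!r}")
    end = aln.position - 1 + aln.ref_consumed()
    if aln.position < 1 or end > genome.chrom_lengths[cidx]:
        raise SamConsistencyError(
            f"{aln.read_id}: alignment [{aln.position}, {end}] exceeds "
            f"{aln.chrom} length {genome.chrom_lengths[cidx]}"
        )


def sam_record_line(aln: Alignment, genome: ReferenceGenome) -> str:
    """Serialize one alignment as a SAM record (after conservation checks)."""
    _check_record(aln, genome)
    if not aln.mapped:
        fields = [
            aln.read_id, "4", "*", "0", "0", "*", "*", "0", "0", aln.seq, aln.qual
        ]
        return "\t".join(fields)
    flag = 16 if aln.strand == "-" else 0
    fields = [
        aln.read_id,
        str(flag),
        aln.chrom,
        str(aln.position),
        str(aln.mapq),
        aln.cigar_string,
        "*",
        "0",
        "0",
        aln.seq,
        aln.qual,
        f"AS:i:{int(round(aln.score))}",
        f"NM:i:{aln.nm}",
    ]
    return "\t".join(fields)


def write_sam(
    alignments: Iterable[Alignment],
    genome: ReferenceGenome,
    out,
    emit_bam: bool = False,
    command_line: str | None = None,
) -> int:
    """Write alignments to SAM (or BAM via pysam); returns the record count.

    Every record is conservation-checked before serialization; output is
    byte-identical across runs for identical inputs (no timestamps).
    """
    out = Path(out)
    header_lines = _sam_header_lines(genome, command_line)
    n = 0
    if emit_bam:
        header = pysam.AlignmentHeader.from_text("\n".join(header_lines) + "\n")
        with pysam.AlignmentFile(str(out), "wb", header=header) as bam:
            for aln in alignments:
                line = sam_record_line(aln, genome)
                bam.write(pysam.AlignedSegment.fromstring(line, header))
                n += 1
    else:
        with open(out, "w") as fh:
            for line in header_lines:
                fh.write(line + "\n")
            for aln in alignments:
                fh.write(sam_record_line(aln, genome) + "\n")
                n += 1
    return n
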