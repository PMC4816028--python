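import random

import numpy as np
import pytest

import _oracles
from conftest import random_dna
from sarmap.extend_cluster import CAL, ExtendedSeed
from sarmap.gap_fill import (
    Alignment,
    MapParams,
    ScoringScheme,
    fill_gaps,
    finalize_read,
    map_read,
    run_batches,
    score_alignment,
    smith_waterman,
)
from sarmap.index import ReferenceIndex, encode_sequence
from sarmap.seeding import Read, reverse_complement

SCHEME = ScoringScheme()


def _read(seq, rid="r"):
    return Read(rid, seq, "I" * len(seq))


class TestSmithWaterman:
    def test_identity_alignment(self):
        score, path = smith_waterman("ACGTACGT", "ACGTACGT", SCHEME)
        assert score == 40  # 8 x match(5)
        assert path.ops == (("M", 8),)
        assert (path.q_start, path.q_end, path.t_start, path.t_end) == (0, 8, 0, 8)

    def test_single_mismatch_case(self):
        # oracle value computed with the independent full-matrix DP
        expected = _oracles.sw_score_oracle("ACGT", "AGGT", 5, 4, 10, 0.5)
        score, _ = smith_waterman("ACGT", "AGGT", SCHEME)
        assert score == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT", SCHEME)
        with pytest.raises(ValueError):
            smith_waterman("ACGT", "", SCHEME)

    def test_n_never_matches(self):
        score, path = smith_waterman("ANNA", "ANNA", SCHEME)
        # best local alignment is a single A=A pair
        assert score == 5
        assert path.ops == (("M", 1),)

    def test_oracle_equivalence_random_pairs(self):
        rng = random.Random(77)
        for _ in range(150):
            q = random_dna(rng, rng.randint(1, 80))
            t = random_dna(rng, rng.randint(1, 80))
            if rng.random() < 0.5 and len(q) <= len(t):
                # embed the query with noise so alignments are nontrivial
                pos = rng.randint(0, len(t) - len(q))
                t = t[:pos] + q + t[pos + len(q):]
            expected = _oracles.sw_score_oracle(q, t, 5, 4, 10, 0.5)
            score, path = smith_waterman(q, t, SCHEME)
            assert score == pytest.approx(expected)
            if path is not None:
                # returned path must reproduce the returned score
                recomputed, *_ = score_alignment(
                    list(path.ops),
                    encode_sequence(q)[path.q_start:],
                    encode_sequence(t),
                    path.t_start,
                    SCHEME,
                )
                assert recomputed == pytest.approx(score)


@pytest.fixture
def indexed_genome(make_reference):
    rng = random.Random(11)
    seq = random_dna(rng, 4000)
    genome = make_reference([("chr1", seq)])
    index = ReferenceIndex.build(genome, k=8)
    return index, seq


class TestFillGaps:
    def test_perfect_cal_yields_full_match(self, indexed_genome):
        index, seq = indexed_genome
        genome = index.genome
        L = 100
        member = ExtendedSeed(0, L, 500, 500 + L, "+", 0)
        cal = CAL(0, "+", 500, 500 + L, [member], L)
        aln = fill_gaps(cal, _read(seq[500:600]), genome, SCHEME)
        assert aln.cigar == [("M", L)]
        assert aln.score == L * SCHEME.match
        assert aln.position == 501
        assert aln.aligned_read_fraction == 1.0

    def test_three_base_deletion_between_seeds(self, indexed_genome):
        index, seq = indexed_genome
        genome = index.genome
        read_seq = seq[1000:1050] + seq[1053:1103]  # 3-base deletion
        cal = CAL(
            0, "+", 1000, 1103,
            [ExtendedSeed(0, 50, 1000, 1050, "+", 0),
             ExtendedSeed(50, 100, 1053, 1103, "+", 0)],
            100,
        )
        aln = fill_gaps(cal, _read(read_seq), genome, SCHEME)
        assert ("D", 3) in aln.cigar
        # score = 100*match - gap_open - 3*gap_extend
        assert aln.score == 100 * 5 - 10 - 3 * 0.5
        assert aln.read_consumed() == 100
        assert aln.ref_consumed() == 103

    def test_unmatched_tail_soft_clipped(self, indexed_genome):
        index, seq = indexed_genome
        genome = index.genome
        rng = random.Random(12)
        tail = reverse_complement(seq[2000:2020])  # unrelated to the locus
        read_seq = seq[300:380] + tail
        member = ExtendedSeed(0, 80, 300, 380, "+", 0)
        cal = CAL(0, "+", 300, 380, [member], 80)
        aln = fill_gaps(cal, _read(read_seq), genome, SCHEME)
        assert aln.cigar[-1][0] == "S"
        assert aln.read_consumed() == 100
        assert aln.aligned_read_fraction <= 0.9

    def test_insertion_read_segment_with_empty_reference_gap(self, indexed_genome):
        index, seq = indexed_genome
        genome = index.genome
        read_seq = seq[600:650] + "ACGTA" + seq[650:700]
        cal = CAL(
            0, "+", 600, 700,
            [ExtendedSeed(0, 50, 600, 650, "+", 0),
             ExtendedSeed(55, 105, 650, 700, "+", 0)],
            100,
        )
        aln = fill_gaps(cal, _read(read_seq), genome, SCHEME)
        assert ("I", 5) in aln.cigar
        assert aln.read_consumed() == 105

    def test_score_recomputes_from_cigar(self, indexed_genome):
        index, seq = indexed_genome
        genome = index.genome
        rng = random.Random(13)
        for _ in range(20):
            start = rng.randint(0, 3800)
            read_seq = list(seq[start : start + 120])
            for _ in range(rng.randint(0, 4)):
                p = rng.randrange(120)
                read_seq[p] = rng.choice("ACGT")
            read = _read("".join(read_seq))
            aln = map_read(read, index, MapParams(seed_length=12))
            if not aln.mapped:
                continue
            oriented = read.sequence if aln.strand == "+" else reverse_complement(read.sequence)
            cstart, _ = genome.chrom_bounds(aln.chrom_idx)
            recomputed, *_ = score_alignment(
                aln.cigar,
                encode_sequence(oriented),
                genome.codes,
                cstart + aln.position - 1,
                SCHEME,
            )
            assert recomputed == pytest.approx(aln.score)


class TestFinalizeRead:
    def _aln(self, score, chrom_idx=0, pos=100, strand="+"):
        return Alignment(
            read_id="r", chrom="chr1", position=pos, strand=strand,
            cigar=[("M", 10)], score=score, mapq=0, aligned_read_fraction=1.0,
            seq="A" * 10, qual="I" * 10, chrom_idx=chrom_idx,
        )

    def test_unique_candidate_gets_mapq_60(self):
        aln = finalize_read([self._aln(100)], _read("A" * 10))
        assert aln.mapq == 60

    def test_tied_candidates_get_mapq_0(self):
        aln = finalize_read([self._aln(100), self._aln(100, pos=500)], _read("A" * 10))
        assert aln.mapq == 0

    def test_mapq_formula(self):
        aln = finalize_read([self._aln(100), self._aln(50, pos=500)], _read("A" * 10))
        assert aln.mapq == 30

    def test_no_candidates_reported_unmapped(self):
        read = _read("ACGTACGT")
        aln = finalize_read([], read)
        assert not aln.mapped
        assert aln.seq == read.sequence

    def test_tiebreak_prefers_leftmost_forward(self):
        a = self._aln(100, pos=100, strand="-")
        b = self._aln(100, pos=100, strand="+")
        c = self._aln(100, pos=900, strand="+")
        best = finalize_read([c, a, b], _read("A" * 10))
        assert best is b


class TestPipeline:
    def test_strand_symmetry(self, indexed_genome):
        index, seq = indexed_genome
        fwd = _read(seq[1500:1650])
        rev = _read(reverse_complement(seq[1500:1650]))
        a_fwd = map_read(fwd, index)
        a_rev = map_read(rev, index)
        assert a_fwd.mapped and a_rev.mapped
        assert a_fwd.position == a_rev.position == 1501
        assert a_fwd.strand == "+" and a_rev.strand == "-"
        assert a_fwd.score == a_rev.score

    def test_unmappable_read_reported_unmapped(self, indexed_genome):
        index, _ = indexed_genome
        aln = map_read(_read("N" * 60), index)
        assert not aln.mapped

    def test_run_batches_order_and_worker_invariance(self, indexed_genome):
        index, seq = indexed_genome
        rng = random.Random(14)
        reads = []
        for i in range(60):
            start = rng.randint(0, 3800)
            reads.append(_read(seq[start : start + 100], rid=f"q{i}"))
        outs = {}
        for workers, batch in [(1, 256), (4, 256), (1, 7), (2, 16)]:
            params = MapParams(batch_size=batch)
            alns = list(run_batches(iter(reads), index, params, workers=workers))
            assert [a.read_id for a in alns] == [r.id for r in reads]
            outs[(workers, batch)] = [
                (a.read_id, a.chrom, a.position, a.strand, a.cigar_string, a.score)
                for a in alns
            ]
        assert len({tuple(map(tuple, v)) for v in outs.values()}) == 1

    def test_empty_stream(self, indexed_genome):
        index, _ = indexed_genome
        assert list(run_batches(iter([]), index, MapParams(), workers=2)) == []
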