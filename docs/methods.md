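# Methods

## Index structure

The reference is held as one concatenated uppercase string over
{A,C,G,T,N}; every chromosome is terminated by a sentinel `$` that sorts
before every nucleotide, so no suffix comparison or pattern match can
cross a chromosome boundary, and suffixes beginning on a sentinel are not
indexed. Characters outside the alphabet (including U) are normalized to
N at load time.

The suffix array is built by prefix doubling over numpy `lexsort`
(O(n log² n) overall), with out-of-range ranks treated as −1 so that a
suffix that is a proper prefix of another sorts first. Correctness is
defined purely by the sortedness postcondition and is checked against a
brute-force suffix sort in the tests.

The prefix table packs each k-mer into a 2-bit-per-base `uint64` key
(hence k ≤ 31; default k = 18) and stores, for every *occurring* N-free
k-mer, its half-open interval of suffix-array ranks — a sparse
compressed-row layout of keys plus interval bounds. Suffixes whose first
k characters contain an N or a sentinel get no entry: seeds never contain
N, and such suffixes remain reachable by the plain binary-search fallback
used for patterns shorter than k. Because two suffixes fall into the same
entry only if their first k characters are identical, each entry's ranks
are provably contiguous in the suffix array; this is asserted at build
time.

Search: patterns with any ambiguous base return no hits. For patterns of
length ≥ k, one sorted-array lookup yields the interval and binary search
inside it resolves the remainder; seeds are k bases long by default, so
the common case is a single lookup. Persistence is a versioned directory
of raw `.npy` arrays plus sorted-key JSON metadata — no timestamps, so
identical inputs serialize byte-identically.

Only the forward strand is indexed; reverse-strand mapping queries the
reverse complement of the read. This halves index memory and is standard
practice among suffix-array mappers.

## Seeding

Seeds of length s (default: the prefix length k) are placed at offsets
`round(i·(L−s)/(n−1))`, i = 0..n−1, with Python's round-half-even
rounding fixed for reproducibility; duplicates collapse, and a read
shorter than s becomes a single whole-read seed. The seed count scales
with read length, `n = max(5, floor(L/s))`, so longer reads receive
proportionally more seeds. A seed with more than `max_hits_per_seed`
(default 100) occurrences is discarded outright rather than enumerated —
a repeat mask that bounds worst-case work.

## Extension

Extension is a greedy symmetric walk: alternately one base leftward then
one base rightward (left first, skipping exhausted directions). A
compared pair that differs, or that involves an N on either side, costs
one mismatch; a direction stops when its next comparison would exceed the
budget or when the read or chromosome boundary is reached. Accepted
mismatches remain inside the span, so extensions are maximal under the
budget. The implementation is vectorized — mismatch offsets are computed
with one array comparison per direction and the alternation is replayed
over mismatch *events* only (the d-th left base is met at tick 2d−1, the
d-th right base at tick 2d) — and is checked against a literal
base-by-base walk oracle. The default budget `ceil(0.04·L)` scales with
read length; raising it can only grow a span (a property test).

## Clustering and CAL selection

Extensions group per (chromosome, strand), are sorted by genome start,
and chain while both the genomic distance between consecutive spans and
their diagonal difference stay within `max_gap` (default 2·L: a CAL must
admit indels and unseeded gaps yet stay local). Envelopes shorter than
`min_cal_length` (default 0.25·L) are discarded. CALs rank by read
coverage (union of member read spans), with ties broken by fewer member
mismatches, leftmost coordinate, then forward strand; the top `max_cals`
(default 5) proceed, which bounds Smith–Waterman work while keeping
enough suboptimal candidates to estimate mapping quality.

## Gap filling and scoring

Within a CAL, same-diagonal overlapping members merge; remaining members
are admitted longest-first and trimmed so the anchor chain is strictly
ordered in both read and genome coordinates. Each inter-anchor gap is
aligned by an affine-gap local Smith–Waterman (a gap of length g costs
`gap_open + g·gap_extend`); because local alignment may not reach the gap
edges, leftover bases adjacent to an anchor pair off as M runs where both
sides have residue and become insertions/deletions otherwise — a
deterministic bridging rule. End gaps search a reference margin of the
gap's read length + 10 bases; read ends the local alignment cannot
reconcile are soft-clipped (never hard-clipped). Traceback ties prefer
diagonal, then deletion, then insertion, starting from the rightmost
maximal cell, so outputs are deterministic; the score kernel is checked
against an independent full-matrix dynamic program on random pairs.

The reported score is recomputed from the final CIGAR and the sequences
(single source of truth, re-verified record by record in the tests). MAPQ
is a deliberately simple margin statistic of this implementation's own
design: 60 for a unique candidate, 0 on a score tie, otherwise
`min(60, round((best − second)/best · 60))`.

`run_batches` processes reads in fixed-size batches (default 256).
Worker parallelism distributes whole batches over a fork-based process
pool; results are collected in submission order, so output is
byte-identical for any worker count or batch size — a contract the tests
enforce — and the pool falls back to sequential execution where fork is
unavailable.

## I/O

FASTQ input may be plain or gzipped (detected by magic bytes); several
files stream in command-line order and their mappings concatenate into
one output. Parsing is Biopython's FASTQ iterator wrapped to report the
file and record number on truncated records or sequence/quality length
mismatches. Output is SAM v1 with `@HD`/`@SQ`/`@PG` headers (no
timestamps), one primary record per read — mapped or unmapped — with
`AS` (CAL score, rounded to integer for the tag) and `NM` tags;
reverse-strand records store the reverse-complemented sequence and
reversed qualities. CIGAR conservation (read-consuming ops equal the
sequence length; the reference span stays inside the chromosome) is
re-checked at write time. BAM output delegates to pysam.

## Simulator

`simulate_genome` draws i.i.d. uniform A/C/G/T bases, split into
near-equal chromosomes — deterministic per seed. `simulate_reads` draws a
uniform position (chromosomes weighted by usable length) and strand, then
applies, in this order: (1) per-base mutations at `mut_rate`, of which a
fraction `indel_frac` are indels (insertion/deletion equiprobable, length
1 + geometric with continuation `indel_ext`, i.e. mean 1/(1−indel_ext))
and the rest substitutions to a different base; (2) reverse
complementation for minus-strand reads; (3) per-base sequencing errors at
`err_rate`, always substitutions, marked Q10 in the quality string
(correct bases are Q40 — a two-level stand-in, not a full quality model).
Reads with more than `max_n` N bases are redrawn. Defaults mirror the
benchmark protocol: mut_rate 0.001 (or 0.01 for the noisy variant),
indel_frac 0.1, indel_ext 0.30, err_rate 0.020, max_n 2. The true origin
is encoded in the read name as `{chrom}_{start1based}_{0|1}_{serial}`
(0 = forward; chromosome names may contain underscores since the name is
parsed from the right).

The evaluator scores a SAM file by `position_pm5` — correct iff
chromosome and strand match and |POS − true_start| ≤ 5 — or by
`coverage80`, which additionally requires ≥ 80 % of the read's bases in M
operations (the long-read rule). Unmapped reads are tallied separately;
percentages are rounded to 2 decimals.

## What the synthetic benchmark shows — and what it does not

The uniform-random genome has essentially no repeat structure, so nearly
every 100 bp locus is unique; accuracy measured here is an upper bound
on, not a reproduction of, accuracy on a real mammalian genome, where
segmental duplications and low-complexity regions create genuinely
ambiguous placements. The acceptance run (1 Mb genome, 10 000 reads at
each of 100/400/800 bp, high-quality noise settings) exercises the full
pipeline — indels split seeds across diagonals and force gap filling;
sequencing errors consume extension budget — at a problem size chosen so
the whole computation completes in well under a minute on one CPU.
Residual misses at 100 bp are mostly reads whose every 18-mer seed is
disrupted on both strands (probability falls steeply with read length)
or whose leading bases sit beyond an indel too close to the read end for
the end-gap alignment to rescue.

## Numerical and degenerate-input choices

- Seed placement uses round-half-even; extension alternation starts left;
  both fixed solely for reproducibility.
- Scores are IEEE doubles; with default penalties all values are
  multiples of 0.5, so equality comparisons in tests are exact.
- An empty CAL list reports the read unmapped (flag 4, `*` fields). A
  pattern containing N returns no occurrences. A gap with an empty
  reference segment becomes an insertion (or a soft-clip at read ends).
- Genomes shorter than k yield an empty prefix table; searches then rely
  on plain binary search.

## Known limitations

Single-end only; one primary alignment per read (no secondary/chimeric
records); no re-seeding of uncovered read regions; no base-quality-aware
scoring; no compressed (FM/BWT) index; the simulator does not model
platform-specific error profiles. MAPQ is a heuristic margin, not a
calibrated error probability.
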