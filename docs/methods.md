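# Methods

## Problem and model

Reference-based FASTQ compression stores each read as a pointer into a
reference genome plus the differences needed to reconstruct it, so its
benefit is governed entirely by how much of a sample's read mass aligns
closely to the reference. For metagenomes no single genome serves: the
community is a mixture of hundreds of species whose composition differs
between cohorts. `cohortref` therefore treats reference construction as a
ranking problem: align a handful of cohort samples against a large basic
catalog of candidate genomes, score each genome by its **mapping rate**

    rate(g) = mapped_best(g) / total_reads

where `mapped_best(g)` counts reads whose single best surviving alignment
lands on genome *g* and `total_reads` counts all QC-passed reads given to
the aligner, and keep the top-N genomes as the cohort-specific reference.
Because each read contributes to at most one genome, the rates over a sample
sum to at most 1, and the cumulative rate of the top-k genomes (the
saturation curve) directly measures the fraction of read mass the reference
will cover.

## Catalog normalization

Assembly gaps are encoded as runs of `N`; we remove **every** `N` character
(not only long runs) and concatenate all segments of a genome, in input
order and without separators, into one complete sequence. This is the
simplest rule that guarantees an N-free emitted reference; its cost is that
a read can span a former gap or segment junction and still align, which at
catalog scale is a negligible artifact and is accepted as such by the test
aligner. Non-N IUPAC ambiguity codes are retained, since deleting them would
remove real sequence. Normalization is idempotent and conserves length
minus the N count exactly.

Sub-database splitting is deterministic greedy bin packing balanced on
total bases (largest genome first, to the currently lightest bin, ties by
genome id and bin index), because aligner index memory scales with bases
rather than genome count. The max/min bin difference is bounded by the
largest single genome.

## Filtering and best-alignment selection

Read-level QC drops reads shorter than 60 bases or containing any N (the
common fastp trimming convention). Post-alignment, a record survives iff
MAPQ ≥ 5, the CIGAR contains none of I/D/N/S/H (`=`/`X` are treated as
match operations equivalent to `M`), and the NM edit distance is ≤ 3 —
since indel CIGARs are already excluded, NM equals the substitution count
on every surviving record. Filters are applied per record first; the best
alignment is then chosen among survivors by higher alignment score
(records lacking an AS score rank below any scored record), then fewer
mismatches, then lexicographically smallest `(genome_id, pos)` — a total
order, so counting is deterministic and independent of record order.
Paired-end mates are counted as independent reads in both numerator and
denominator: the method needs read mass, not fragment identity, and this
keeps the statistic aligner-agnostic.

Real aligners assign low MAPQ to multireads, which partially pre-empts the
best-alignment step; the thresholds are exposed as configuration
(`FilterConfig`) so users can match their aligner's conventions. The
built-in test aligner emits MAPQ 60 for every mapped record precisely so
the MAPQ filter never masks the multi-mapping selection path in tests.

## Pooling and sub-database integration

Cross-sample aggregation pools counts (summed numerators over summed
denominators) rather than averaging per-sample rates; pooling is then
associative — any partition of the sample set yields the identical table —
and robust to unequal sequencing depth. When the catalog is split, each
sub-database run retains every read's surviving best record; integration
re-applies the same selection across sub-databases, which is provably
equivalent to the monolithic run because the selection key is a total order
and the genome sets are disjoint (verified exactly in the test suite).
Zero-count genomes are excluded from the ranking proper and used only to
pad a top-N request that exceeds the number of mapped genomes (padding in
genome-id order, logged).

## Built-in aligner

Ungapped seed-and-extend: the catalog is hashed by every k-mer (default
k = 21, minimum 11); each read is seeded by its non-overlapping k-mers on
both strands, and every distinct candidate locus is scored by full-read
Hamming distance, reported with CIGAR `<len>M`, `NM` = distance and
`AS = len − 5·NM`. For a read of length ≥ (m+1)·k, a locus with ≤ m
substitutions always retains one exact seed, so at the pipeline's mismatch
ceiling (3) all 100-base hits are found — the test suite checks exact
agreement with an exhaustive per-offset Hamming scan. The aligner is a
testing device: production alignment is delegated to external SAM-emitting
tools.

## Codec

The demonstrator codec covers the sequence stream only; read IDs and
quality strings pass through to the entropy stage untransformed, since
reference choice affects only sequence (quality scores dominate FASTQ size
and compress poorly regardless). Each read is REF-encoded when its best
ungapped hit has at most `max_diffs` substitutions (default 3, mirroring
the filter ceiling), storing genome index, 1-based position, strand, length
and the substitution list (delta-coded offsets); otherwise it is stored RAW
(2-bit packed for pure ACGT, literal bytes when other characters occur, so
the fallback is universal and the round trip is lossless for arbitrary
input). Records are serialized with varints and the whole body is
zlib-compressed (level 9). The container header carries a magic number,
version and an MD5 of the reference's (id, sequence) pairs; decoding with a
non-identical reference is refused. Compression ratio is defined as
original file bytes / compressed file bytes, measured on whatever file the
user supplies (gzipped inputs are therefore compared at their on-disk
size). The native ratios demonstrate the directional benefit of a matched
reference; they are not comparable to ratios of full-featured production
compressors, whose gains also come from header/quality modeling.

## Synthetic communities

The simulator generates i.i.d. uniform-ACGT genomes (optionally re-emitted
with inserted N-run gaps and split into segments, to exercise
normalization), a lognormal(0, σ) abundance profile normalized and sorted
descending (default σ = 1.5, which reproduces the qualitative skew of real
shotgun communities — a small minority of species carrying most of the
abundance, abundant-species proportion typically well below 25% — without
claiming any specific cohort's values), and paired-end reads: genome drawn
proportional to abundance, fragment start uniform, insert length normal
(default 300 ± 30), mate 1 forward / mate 2 reverse, substitution errors
i.i.d. per base (default 0.5%), with optional per-read single 1-base indels
and single N bases as explicit knobs for exercising the CIGAR and QC
filters. Truth rows carry 1-based positions on the normalized genome,
matching SAM. Defaults keep reads at 100 bases so QC passes unless
deliberately violated.

What random genomes do **not** emulate: homology and shared k-mers between
related species, GC and coverage bias, quality-dependent error spectra, and
real multi-mapping structure. Passing tests therefore demonstrate the
correctness of the filtering/ranking/codec machinery and the recoverability
of abundance rankings under sampling noise, not performance on real
communities.

The abundant-species statistic sorts abundances in decreasing order and
returns m/n where m is the smallest prefix whose cumulative abundance
reaches the threshold (default 80%); the species that first crosses the
threshold is included (the boundary convention), and a 1e-12 slack guards
the comparison against floating-point accumulation.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen so that
sampling noise is far below the effects being measured: the ranking
recovery check uses 20 genomes × 50 kb with five samples of 50,000 pairs
(≥ 150× depth on abundant genomes; the rank-5/6 abundance gap is asserted
to exceed twice the binomial standard error before the check runs), the
aligner oracle uses 5 genomes × 5 kb with 500 reads, sub-database
equivalence uses 30 genomes with k = 3, and the codec check uses 10,000
reads. The acceptance script simulates 20 genomes × 30 kb with three
samples of 20,000 pairs. Mapping-rate equality is asserted to 1e-12;
saturation monotonicity to 1e-15 per step; all randomness flows from
explicit seeds.

## Known limitations

- The built-in aligner is ungapped and quality-blind; indel-carrying reads
  are meant to be rejected (or RAW-encoded), not rescued.
- The codec does not model read IDs or quality strings and its ratios are
  not comparable to production reference-based compressors.
- Selection of which cohort samples to use for construction is the
  caller's; the package only provides deterministic pooling of whatever is
  given.
- Third-generation (long, high-indel) reads are out of scope throughout.
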