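# Methods

## The chromosome-quotient model

The classifier assumes an XX/XY karyotype and a contig assembly in which
each contig derives wholly from one chromosome class (autosomal, X or Y).
Per diploid cell the copy numbers are female A=2, X=2, Y=0 and male A=2,
X=1, Y=1, so when both sexes are sequenced to the same fold-coverage of
their own genome, the library-normalized female:male ratio of per-contig
read counts (the chromosome quotient, CQ) has expectation ≈2 on X, ≈1 on
autosomes and ≈0 on Y.

The alignment criterion feeding the ratio is deliberately extreme — the
entire read must occur in the contig with zero mismatches on either strand
— because false cross-chromosome mappings, not sensitivity, are the danger
for a depth-ratio statistic. A read occurring several times in one contig
counts once for that contig but may count in several contigs; this damps
within-contig repeat inflation while leaving cross-contig repeat behaviour
visible in the counts.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `y_max` | 0.05 | Y call: CQ strictly below this (half-open band) |
| `x_min`, `x_max` | 1.9, 2.5 | X call: closed interval `[x_min, x_max]` |
| `min_male_hits` | 20 | below this male count the CQ is undefined ("low-evidence") |
| `normalize` | on | divide counts by library totals before the ratio |
| `seed_k` | 31 | seed k-mer length of the exact-match index |

The X band is read as inclusive ("between 1.9 and 2.5"); the Y band as
exclusive ("less than 0.05"). The `min_male_hits` floor is a design choice
of this implementation: with a handful of male hits the ratio is dominated
by Poisson noise and arbitrarily small denominators would flood the X band,
so such contigs are reported separately instead of being classified or
assigned an infinite CQ. Normalization defaults on because it is a no-op
for equal library sizes and makes the statistic portable when totals
differ (e.g. resequencing one sex deeper leaves labels essentially
unchanged).

## Exact-match counting

The index stores every seed k-mer (default k=31, 2-bit packed into uint64)
of every contig in a sorted array with its contig and offset. A read is
looked up by its first k-mer and by the first k-mer of its reverse
complement; candidate sites are verified by direct string comparison, so
results equal a naive full scan exactly — the seed stage only prunes. If a
read occurs somewhere, its first k-mer occurs at that site, so seeding
loses nothing. Reads shorter than the seed fall back to a per-contig
substring scan. N is unmatchable on both sides: reads containing N are
never counted, and contig positions under an N can never verify.

## Read simulation

Read origins are drawn with probability proportional to
`copy_weight(class) × (contig_length − read_length + 1)`, starts uniform
within the contig, strands equiprobable. The read count is
`round(depth × H / read_length)` with `H = Σ w_c·len_c / 2` the
copy-weighted haploid-equivalent genome length, so `depth` is the expected
autosomal coverage in both sexes and summed read bases equal `depth × H`
to within one read. Errors are uniform per-base substitutions; the error
model is substitutions-only because under a zero-mismatch full-length
criterion an indel and a substitution have the identical effect (the read
no longer matches), so substitutions are the only error mode that changes
behaviour. Three RNG streams (positions, error positions, error bases) are
derived from the seed with `SeedSequence`, so raising only the error rate
perturbs a superset of the lower rate's error sites — that makes the
mapped-fraction-vs-error-rate monotonicity testable path-by-path rather
than only in expectation.

The per-sex fold-coverage convention (each sex sequenced to `depth` over
its own haploid-equivalent length) mirrors the equal-half-lane design of
sex-pooled sequencing and makes the expected autosomal CQ equal 1 up to
the small difference between the two sexes' weighted genome lengths.

## Planted transposable elements

A planted copy is the family consensus evolved under a true Kimura
2-parameter Markov process: with ts/tv ratio R and target divergence d
(expected substitution events per site), the per-site column probabilities
are computed from the matrix exponential of the K2P rate matrix with
transition rate `α = dR/(R+1)` and per-partner transversion rate
`β = d/(2(R+1))`. Multiple hits therefore occur at the model's rate, and
the K2P estimator applied to the realized alignment is a consistent
estimator of d — at d=0.20 the raw mismatch fraction is only ≈0.173 while
the K2P estimate recovers ≈0.200. Copies overwrite a uniformly chosen
non-overlapping contig window (replacement keeps coordinates stable and
needs no re-indexing); the realized divergence of every copy is recorded
in the truth table. Copies are planted on the forward strand; strandedness
is irrelevant to divergence estimation.

## Divergence landscape

Each alignment contributes its aligned (countable) columns, not its
genomic span, to the bin containing `100·K` — the same weighting the
per-alignment divergence outputs of standard repeat annotators use. Only
columns with a standard base on both rows are counted; gap and N columns
are excluded from both numerator and denominator. Alignments whose P, Q
fall outside the estimator's domain (`1−2P−Q ≤ 0` or `1−2Q ≤ 0`) are
reported in a separate saturated bucket rather than clamped into the top
bin, which would silently inflate old-element bins. The x-axis is capped
at 55% by default; because defined K2P values above the cap exist, the top
bin is open-ended so that binned bp always conserve the aligned bp of
defined-divergence alignments. No CpG-adjusted variant is offered — plain
K2P only. Repeat fractions merge overlapping annotation intervals per
sequence before summing, so double-annotated bases count once.

The production input is a minimal TSV (contig, 1-based inclusive
coordinates, family, class, and the two gapped alignment rows); a
best-effort parser for cross_match-style `.align` blocks is included. For
simulated data the pipeline re-aligns each planted copy to its consensus
with a global affine-gap aligner (match +2, mismatch −2, gap open −5, gap
extend −1 per gapped column; Biopython `PairwiseAligner`, first optimal
alignment in its deterministic enumeration order), exercising the same
path real alignments take.

## Assembly metrics

N50 follows the descending cumulative-sum convention with boundary ties
resolved to the contig crossing the half-total. %AT is computed over
A/C/G/T calls only — N density is reported separately as N's per 100 kb of
total length (N included in that denominator), so the two metrics stay
independent; at realistic N densities the alternative denominator changes
%AT by well under 0.1 point.

## Pipeline determinism and problem sizes

All randomness flows from one top-level seed through named
`SeedSequence` children (genome, TE families, female reads, male reads),
so stages are reproducible in isolation and a rerun with the same config
is byte-identical (the manifest records a SHA-256 per artifact; no
timestamps enter any output). The validation study used throughout the
tests and the acceptance script simulates 200 contigs (140 A / 30 X /
30 Y, 5–50 kb, GC 0.28), both sexes at 20×, 100 bp reads and 0.5% error —
about 5.5 Mb of contigs and 1.9 M reads, a size chosen so the full study
runs in well under a minute while leaving per-contig counts deep enough
(hundreds to thousands of hits) for the CQ bands to separate cleanly.

## What the simulation does and does not show

The generator reproduces the features the CQ statistic actually consumes —
copy-number-weighted depth, sequencing error, fragmented contigs, planted
repeats at known divergence — and passing tests demonstrate that the
statistic, thresholds and estimators behave as designed under those
assumptions. It does not model allelic variation within pooled
individuals, GC-coverage bias, indel or structural errors, paired-end
structure, quality-score variation, or contigs of mixed chromosomal
origin (chimeric assemblies). On real data those effects widen the CQ
distributions — pooled polymorphism in particular reduces the mapped
fraction unevenly between sexes — so real-data recall at the default
bands should be expected to be somewhat lower than the near-perfect
recovery seen in simulation. The smallest simulated contigs (≈5 kb at
20×) already show the dominant real-data failure mode: counting noise
pushes a few true-X contigs just below the 1.9 cutoff.

## Numerical and degenerate-input choices

CQ is reported as NaN (never ±inf) when undefined; classification of a
NaN CQ always yields low-evidence. `k2p_distance` raises on impossible
fractions (negative, or P+Q>1) but returns NaN, not an error, at
saturation. Empty reads are skipped with a logged warning; duplicate
contig ids, mismatched contig universes, zero-contig genomes, annotation
intervals beyond sequence ends and non-positive bin widths are rejected
loudly. Interval coordinates are 1-based inclusive in every on-disk
format; internal arrays are 0-based.
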