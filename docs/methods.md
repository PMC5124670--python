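# Methods

## Detection model

A back-splice junction is a chimeric alignment whose acceptor coordinate is
genomically upstream of its donor on the same chromosome and strand. The
caller is annotation-guided and coordinate-based: it never inspects read
sequence, only junction coordinates against gene models. Two event classes
are called, in fixed priority order:

1. **Exonic circRNA.** The acceptor matches an annotated exon start and the
   donor an annotated exon end of the *same* transcript, each within a
   tolerance τ. The candidate spans the enclosed exon run; its coordinates
   are snapped to the annotated boundaries and its exon block structure
   (sizes, offsets) is copied from the annotation. Snapping makes junction
   keys annotation-stable: the key never depends on τ or on aligner endpoint
   wobble.
2. **ciRNA (circular intronic RNA).** Both coordinates fall inside one
   annotated intron and the junction's 5' end lies within τ of the intron's
   donor boundary — the intron's genomic start on `+` transcripts, its
   genomic end on `-` transcripts. This is the geometry of an intron lariat
   circularised at the branchpoint: the donor side is fixed by splicing, the
   branchpoint side is free, so only the donor side is snapped. Intron
   containment is closed at both ends because under half-open exon intervals
   the intron end *is* the shared boundary with the downstream exon.

Records failing both are dropped and counted by reason (cross-chromosome,
strand mismatch between segments, linear orientation, unmatched). Exonic
evidence beats intronic when a key is observed as both, because an
exon-boundary match is the more specific explanation.

Tie-breaking when several transcripts match both boundaries: the transcript
yielding the most exons within the span wins, then the lexicographically
smaller transcript id. This is deterministic and favours a complete exon
composition for the reported isoform.

**Assumptions and limits.** Detection requires an annotation; novel
(unannotated-boundary) circles are not called. Fusion-like cross-chromosome
events are out of scope. The caller assumes the chimeric record's two
segment strands agree and equal the transcript strand; the simulator emits
reads that way, and real dialects that encode the mate orientation
differently would need a one-line adapter at parse time.

## Filters

- **Support filter:** keep junction keys with at least k *distinct* read
  identifiers, default k = 2. Duplicate read ids at a key count once.
- **polyA+ subtraction:** remove any key predicted in *any* poly(A)+ sample
  at *any* read count (a single polyA+ read convicts). Rationale: true
  circRNAs are nonpolyadenylated, so a poly(A)-selected prediction marks a
  library-prep or alignment artifact. The reference set is the union over
  all polyA+ samples declared in the sample sheet.

Both filters are monotone set operations on disjoint criteria (one reads a
count, the other a key's membership elsewhere), hence idempotent and
commuting; this is property-tested. The pipeline fixes the order
support-then-subtraction purely for reproducible stage logs.

## Quantification

SRPBM = raw junction reads / total mapped reads × 10⁹; RPM uses 10⁶. The
denominator is the per-sample total mapped reads from the sample sheet (not
junction-spanning reads only) — the plain reading of the definition and the
only depth the pipeline sees. Matrices keep NaN for "key never observed in
this sample", distinct from an observed zero; TSV output encodes it as
`NA`. The reporting transform is log10(value + 1), chosen to pass through
zero; no inference depends on this choice.

## Statistics

- **Spearman's rho** is the Pearson correlation of mid-ranks (average ranks
  at ties). The p-value is an exact full-permutation p for n ≤ 10 (the
  permutation distribution of rho given the observed, possibly tied, rank
  vectors) and the t-approximation with n − 2 df above. Exactness matters
  at the n = 4–6 typical of paired-lesion expression comparisons; the n ≤ 10
  bound keeps the enumeration (≤ 10! pairings, vectorised) to a few
  seconds at worst.
- **Wilcoxon–Mann–Whitney**: U on mid-ranks for the first sample. For
  n₁ + n₂ ≤ 12 the p is exact by enumerating all C(n, n₁) group
  assignments — correct under ties, unlike the classical no-tie recursion —
  with two-sidedness defined by |U − n₁n₂/2| ≥ |U_obs − n₁n₂/2| (so
  identical samples give p = 1 exactly). Larger samples use the
  tie-corrected normal approximation.
- Equal-to-threshold comparisons in both exact tests use a 1e-12 slack so
  floating-point mid-ranks cannot drop tied arrangements.
- **Group summaries** operate on the union of distinct junction keys over a
  group's samples. Fractions are always reported with explicit
  numerator/denominator. The length histogram uses fixed 2500-nt bins from
  zero (reporting emphasis at 12 500 nt). The length~exon-count association
  is one-tailed (positive), since multi-exon circles are mechanically
  longer. No multiple-testing correction is applied anywhere.
- **Overlap** partitions keys into common-to-all-groups, exclusive-to-one,
  and (with ≥ 3 groups) partial; the three parts tile the key universe, a
  property tested on random inputs.
- circRNA–mRNA correlations use pairwise-complete observations and require
  ≥ 3 complete pairs.

## Synthetic cohort generator

The generator emulates a paired-lesion total-RNA design with a poly(A)+
control: by default ten total-RNA samples in two groups of five (depths
27.5–35 M mapped reads, a realistic bulk RNA-seq range) plus one poly(A)+
library, 40 planted exonic circles, 10 intron lariats, 8 artifact junctions
and 20 linear decoys on 30 genes over 3 chromosomes, with 2–10 supporting
reads per planted junction. Depth values are free parameters of the design;
the defaults are ordinary bulk totals.

Plant geometry mirrors the caller's definitions exactly: exonic plants are
whole exon runs of one transcript (1 up to all exons, so compositions up to
16+ exons are reachable on a 16-exon model); lariats sit in one intron with
the 5' end at the donor boundary. Each circle is guaranteed present in at
least one total sample and enters each further total sample with
probability 0.7, giving non-trivial overlap structure. **Artifact junctions
are emitted into every sample, poly(A)+ included**: they model library-prep
artifacts present in both preparations, are back-splice-shaped so they
survive the caller and the support filter, and can only be removed by the
subtraction — which is precisely what the end-to-end recovery test
isolates. Linear decoys are ordinary forward splice junctions and exercise
the orientation rule.

Reads are identifiers only (`<sample>:<key>:<i>`); "independent reads"
means distinct identifiers. What the generator does *not* model: sequencing
error, alignment ambiguity, endpoint wobble (emission is exact, so
end-to-end tests run at τ = 0), expression covariance between samples, and
RNase R enrichment. Passing the recovery test therefore demonstrates the
correctness of the calling/filtering logic, not robustness to alignment
noise — the latter is covered separately by the snapping/tolerance unit
tests.

Determinism: all randomness flows from `numpy.random.default_rng` seeded
per stage from the config seed; all file writes are explicitly ordered, so
identical configs give byte-identical outputs (tested).

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; length = end − start. The
  published hg19 rows used in the acceptance checks confirm this convention
  reproduces every printed length exactly.
- Default τ = 2 nt absorbs small aligner endpoint wobble; τ = 0 is used
  wherever emission is exact. The candidate key set grows monotonically
  with τ (tested on the fixture).
- One published multi-exon row prints an exon count inconsistent with its
  exon-size list (a likely thousands-separator typo); only its span length
  is used, never its composition.
- Degenerate inputs: empty junction files yield empty candidate lists;
  empty groups yield zero-count summaries with the correlation explicitly
  flagged undefined; constant vectors raise rather than return NaN.

## Problem sizes

The test suite's end-to-end cohort uses 6 samples × 200 planted junctions;
oracle-equivalence suites use 100 randomised instances of ≤ 20 transcripts
and 50–60 records; filter-law suites use 1000 random profiles. These sizes
give full coverage of the combinatorics (every drop path, tie case and
filter interaction) while keeping the whole suite under two minutes.
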