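# Methods

## Scope and model

`varscreen` scores candidate variants (SNV, insertion, deletion; normalized
to minimal left-aligned form) against their read pileup. Germline mode
computes 16 metrics from one track; somatic mode adds a matched normal
track, detects potential germline alleles there, and appends two
normal-track metrics. Tags, the weighted v-score, F_β threshold selection
and the XGBoost refinement classifier operate purely on these metric
vectors. The polarity convention is fixed throughout: metrics measure
artifact risk, so a **low** v-score marks a likely true variant, and the
threshold sweep classifies `vscore < t` as retained-true (strict `<`,
smallest threshold on F_β ties).

## Read handling

- Reads are retrieved per locus through the BAM index (logarithmic in track
  size); a brute-force linear scan is the test oracle for equivalence.
- Duplicates, secondary, supplementary and unmapped records are excluded
  before any counting — this matches what a default review track displays.
  The duplicate filter can be disabled (`ThresholdConfig.exclude_duplicates`).
- Support classification walks the CIGAR: an SNV is supported when the
  aligned base at the locus equals the alternate; an insertion when an
  insertion of exactly the inserted sequence opens immediately after the
  locus; a deletion when a deletion of exactly the deleted length starts
  immediately after the locus. A read whose deletion spans the locus covers
  it (counts toward d) without supporting.
- Head/end distances are measured in aligned-reference space from the
  first/last aligned (non-clipped) base, strand-aware (the head of a
  reverse-strand read is its rightmost aligned base). Soft-clipped bases are
  invisible to these distances, as they are in review practice.
- Base qualities are not used anywhere; they are a possible future filter.
- Mate spans come from the MC tag when present, otherwise the mate is
  assumed to span one read length from its start.

## Metric details and numerical choices

- **Boundaries.** "Distance under threshold" means ≤ `near_dist` (default
  5 bp); "MAPQ under threshold" means strictly < `mapq_thr` (default 10).
  Both are configurable and both boundary cases are unit-tested.
- **Adjacent indels** are counted per supporting read (a read contributes at
  most 1 to each of d_insert and d_del), keeping ni, nd ≤ 1 since they are
  divided by d_m. The candidate's own indel event never counts as adjacent.
- **mm.** The window is the 20 reference positions within ±10 bp of the
  locus, the locus itself excluded (n shrinks only at contig edges).
  Mismatch frequency is depth/d, and only frequencies strictly below
  `mm_freq_thr` (default 0.05) enter the sum; recurrent mismatches belong to
  hdr instead.
- **hdr.** HR = 2h/(d_m + d_i) is computed for every cataloged mismatch
  co-occurring with the candidate on at least one read. When HR_max ≥ 0.9
  the score sums only the HRs that themselves reach 0.9 — summing
  sub-threshold HRs would let many weakly linked mismatches inflate the
  score, contradicting the tag's intent. Two fully concordant mismatches
  therefore give hdr = 2.0, the designed above-one case.
- **mv** counts reads (not distinct alleles) carrying a non-reference,
  non-candidate allele at the locus, consistent with the companion tag rule
  d_mv ≥ 2; the distinct-allele count is kept as a diagnostic. In somatic
  mode, alleles established as germline from the normal track are excluded.
- **si.** d_p counts paired supporting reads; d_si those whose locus falls
  inside the mate overlap. Defining d_p as "mate also covers" would force
  si = 1 whenever defined, so the paired-read denominator is used.
- **Repeat flags.** A tandem repeat is a tract of a primitive unit of length
  1–5 with ≥ 5 copies for homopolymers and ≥ 4 otherwise, within ±10 bp of
  the locus; these thresholds are config values because no canonical numbers
  exist. `ri` accepts any whole number of copies of a cyclic rotation of
  the unit (left alignment makes the rotation arbitrary); `li` requires an
  insert of ≥ 20 bp duplicating the reference immediately before or after
  the locus.
- **Degenerate pileups.** d = 0 yields lcr = vafr = 1 (maximal risk) with a
  warning; d_m = 0 yields zero rates; d_p = 0 yields si = 0.

## Somatic mode

Every non-reference allele key observed in the normal pileup with ≥ 2
supporting reads is scored with the germline metric set, using `thr_n` as
the coverage requirement; alleles with v-score ≤ 3.5 are treated as
germline. The cutoff sits at the midpoint of the empirically robust 3–4
threshold band and is configurable. nvaf = d_n/d_normal and
lncr = 1 − min(thr_n, d_normal)/thr_n depend only on the normal track
(property-tested by mutating the tumor pileup). With an empty germline set,
somatic and germline scoring agree exactly on the 16 shared metrics.

The VN tag rule is implemented as `nvaf ≥ 0.1 × thr_vaf ∧ d_n ≥ 2`. The
alternative reading `nvaf ≥ 0.1 × thr ∧ d_normal ≥ 2` is dimensionally
inconsistent (thr is a read count) and total coverage alone cannot signal
the allele's presence in the normal; it remains selectable via
`ThresholdConfig.vn_literal`.

## Scoring, tags, evaluation

Default weights: 3 for lcr, vafr, lm, ni, nd; 2 for lncr, mv, hdr; 1 for
everything else (the third level is unnamed, so it is fixed at 1). Weights
are user-overridable. Tag predicates are exactly the quantitative standard
in the scoring table; RI implies RR in the output since a repeat region is
its prerequisite. Threshold sweeps cover 0 to max(vscore) inclusive at the
given step (default 0.1); precision/recall are reported as 0 with a warning
when a confusion marginal is empty, and MCC is 0 when its denominator
vanishes.

## Refinement classifier

Features are the metric vectors in a fixed, model-embedded column order
(16 germline, 18 somatic; absent somatic columns are never silently filled).
Protocol: XGBoost binary-logistic, grid {0.01, 0.05, 0.1} × {0.1, 1, 10} ×
{3, 6, 9} for learning rate, gamma and max depth (27 points), 10-fold
stratified CV selecting the best mean fold AUC (the selection statistic is
unstated upstream; AUC matches how the model is evaluated), refit on the
full data. Boosting rounds default to 100 — the library default is kept
deliberately. Fold assignment and training are seeded; identical seeds give
identical hyperparameters, predictions and model hashes. AUC is the
Mann–Whitney rank statistic with averaged ties; the test oracle is
exhaustive pair counting.

## Synthetic data

The generator emulates 100 bp paired-end FR reads, fragments 300 ± 30 bp
(clipped to [220, 380]), MAPQ 60, depth 50 and VAF 0.5 unless a signature
dictates otherwise. Each of the 19 tags has one signature that plants its
artifact at a controllable intensity; canonical super-/sub-threshold
conditions are encoded in `ArtifactSpec.for_signature` (e.g. low-coverage
uses depth 8 vs 30 around the default thr = 15; the low-MAPQ weak case uses
intensity 0.1 because the LM tag already fires at lm ≥ 0.2). The
short-insert signature uses 160 bp fragments so mates overlap at the locus.
Supporter placements are drawn without replacement so span-duplication
stays low except when deliberately planted; strands alternate exactly
except for the strand-bias signature. Reference contigs are random with a
fixed GC of 0.45; windows around non-repeat variants are re-randomized
until the repeat scanner finds no tract near the locus, and repeat
signatures embed explicit tracts. Truth labels follow the simulation
convention artifact ⇒ false positive.

The generator does **not** model base-calling errors, quality-score
structure, alignment ambiguity or GC bias. Passing tests therefore
demonstrate that the metrics, tags and classifier respond correctly to the
artifact geometries they target — not that the default thresholds are
optimal for any particular instrument or pipeline.

## Pipeline determinism

Per-variant scoring is a pure function of the input files and configuration.
Parallel runs chunk variants round-robin across workers and reassemble
results by variant index, so output files are byte-identical for any worker
count; the worker count is the one configuration value echoed only to the
log, never into output headers. Thresholds default to the documented
somatic exome settings (thr = 15, thr_n = 5, thr_vaf = 0.15).

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
500 randomized pileups of ≤ 30 reads for oracle equivalence and the range
law, single-variant pileups for the 19-tag closed loop, 200–300 variant
datasets for sweeps, classifier training and parallel-determinism checks.
These sizes fully exercise every code path while keeping any run to seconds.

## Known limitations

- Multi-nucleotide polymorphisms mimic the hdr signature and are not
  separately modeled.
- CRAM input, realignment, phasing and streaming of unindexed files are out
  of scope.
- The normal-track germline detector scores allele keys observed at the
  locus (bases, insertions, deletions anchored there); complex nearby
  haplotypes are not joined.
- Somatic contamination fractions are not estimated; the VN tag only flags
  the pattern.
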