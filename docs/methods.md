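# Methods

## Data model and conventions

All coordinates are 0-based, half-open. A CpG call is the pair
(methylated count, total count) at the forward-strand C position;
coverage files reporting the two strands separately can be merged at
ingestion (`destrand=True`), which folds a call at position *p*+1 into an
existing call at *p*. Single cells at ~1× coverage carry almost exclusively
depth-1 (binary) calls; bulk controls carry real depth. Sample metadata
(genome label, cell count, group, aligned read count) rides on the sample
object and comes from a plain sample-sheet TSV.

## Read-level processing

Bisulfite treatment converts unmethylated cytosines to thymine. A genomic
read whose non-CpG cytosines were largely *not* converted is evidence of a
failed conversion or a contaminating (non-bisulfite) fragment; reads with
fewer than three converted non-CpG cytosines are discarded. Reads with zero
non-CpG cytosines cannot demonstrate conversion and are likewise discarded
— the predicate "fewer than three converted" is simply true for them.
Spike-in reads are exempt: the unmethylated spike-in oligo is precisely the
instrument that measures failed conversion and must not be censored by the
very filter it calibrates.

PCR duplicates are removed keying on (chrom, start, end) only — no strand,
mate, or quality information — keeping the first read in input order, which
makes the operation deterministic. Conversion filtering and deduplication
commute when duplicates are exact copies of their source fragment (the PCR
model); they need not commute for coincidentally co-located reads with
different conversion counts, so the pipeline applies filter first, then
dedup. Conversion-rate QC runs **before** deduplication: spike-in reads
align to a short oligo reference at near-identical coordinates and
position-based deduplication would collapse them.

Conversion rates pool all cytosine observations on the spike-ins, CpG and
non-CpG alike, because the oligo methylation state is known by design:
under-conversion = C-observations still read as C on the unmethylated
oligo; over-conversion = C-observations read as T on the methylated oligo.
Rates are flagged missing (None) when a class has zero observations rather
than defaulting to 0, which would be indistinguishable from a perfect
library.

## Region-set aggregation

The set summary is a mean of means: per region, the *unweighted* mean of
the covered per-CpG methylation fractions; per set, the unweighted mean of
the covered region means. Unweighted per-region pooling matches the
"mean across CpGs" reading and keeps bulk controls (deep, uneven coverage)
comparable with single cells; at depth 1 the two weightings coincide.
Regions without a covered CpG are skipped, never zero-filled. A CpG inside
k overlapping regions of one set contributes to each containing region —
an interpretation, since overlap handling is genuinely underdetermined.
Containment is half-open: a CpG at position end−1 belongs, at end does not;
a CpG whose G falls just outside the region still counts, because the
dinucleotide *start* is inside.

The support filter keeps a set only if the per-sample CpG-measurement count
has minimum ≥ 100 AND mean ≥ 200 across *all* samples in the analysis
(controls and treated alike) — the only reading that uses both thresholds.

CpG-percent annotation accepts either a per-chromosome sorted array of CpG
start positions or raw sequence (dict or FASTA via pyfaidx); a region on a
chromosome missing from the source counts as 0 CpGs and still enters the
unweighted mean, rather than erroring on incomplete references.

## Residual model and trajectory

Per sample, OLS of (value − control mean) on (1, control mean, CpG
percent), fitted by `numpy.linalg.lstsq` over every region set with a
complete triple — not only the sets that later turn out testable. At least
3 complete sets and a full-rank design are required; rank deficiency
reports which predictor is degenerate. Residuals are exactly mean-zero and
orthogonal to both predictors (checked to 1e−8 in tests).

Differential selection uses a two-sided two-sample t-test per set, Welch
(unequal variance) by default because single-cell groups are small and
heteroskedastic; an equal-variance flag exists. No multiple-testing
correction is applied by default (the cutoff is a pre-defined raw p < 0.01);
a Benjamini–Hochberg option is available. The "up to 20" cap applies per
direction (up to 20 positive and 20 negative), with deterministic
tie-breaking: p ascending, |mean difference| descending, set name ascending.
Sets with fewer than two residual values in either group are skipped and
counted.

Lineage scores average the selected sets per sample: y over positive sets,
x over negative sets. Two score modes exist — "residual" (default) averages
residuals; "methylation" averages the raw matrix values over the same sets —
because both summaries are legitimate and emphasize different things
(deviation from expectation versus absolute level). Selection is fitted on
endpoint versus control only; scores are computed for every sample, so
intermediate time points are placed without having influenced the model —
the basis of the interpolation check (multiplier-0.5 groups land between
the extremes, Spearman |ρ| ≥ 0.9 with the effect multiplier; note the
negative-set score *decreases* with treatment, so its correlation with time
is negative).

## QC analytics

**Saturation**: per iteration a uniform random permutation of samples;
step k plots cumulative aligned reads (from the sample sheet — fragments,
not covered positions) against the size of the union of covered positions.
Ten iterations by default; mean and population SD per step. The final point
is permutation-invariant and exactly the union size; the unit tests compare
the Monte-Carlo mean against the exhaustive average over all 120
permutations of 5 samples.

**Alignment ratio**: expected human-read fraction from sorted cell counts
weighted by genome size (defaults 3.10 Gb human / 2.73 Gb mouse,
overridable); pass iff observed odds are within a symmetric 2-fold band of
expected odds. The band width is a configurable stand-in — no published
width exists.

**Copy-number concordance**: CN-annotated regions overlapping any exclusion
region are dropped whole (no trimming). Per class, coverage = total aligned
bases in class regions / total region length (bases counted with
multiplicity, i.e. mean depth); normalized by diploid coverage, so diploid
is exactly 1 whenever defined and NaN otherwise.

**MDS**: classical Torgerson scaling — double-center the squared Euclidean
distance matrix, eigendecompose, scale the top-k eigenvectors. Distances
use pairwise-complete features rescaled by √(total/shared features),
because complete-case intersection across sparse single cells is too small;
`min_sample_fraction` (default 1.0 = complete features only) trades
coverage against completeness. Axis signs are fixed by making each axis's
largest-magnitude coordinate positive, so output is reproducible up to
nothing. Within-group variability is the mean pairwise distance over
unordered within-group pairs, with the same distance definition.

## Simulator: the stated world

The generator is a deliberately *scaled-down* world, not a miniature
mammalian genome:

| parameter | default | why |
|---|---|---|
| genome | 2 chromosomes × 2 Mb | desk-scale runtimes |
| region sets | 50 sets × 40 regions × 500 bp | enough sets to exercise selection and filtering |
| CpGs per region | mean 10, per-set density factor U(0.4, 1.6) | region sets genuinely differ in CpG density (CpG-poor enhancers to CpG-rich promoters); a constant density would make the CpG-percent predictor degenerate |
| background CpG density | 0.002 /bp | sparse inter-region CpGs |
| baseline methylation | Beta(0.5, 0.5) per set | bimodal, as methylomes are |
| global effect | −0.3 (linear scale, clamped) | a strong demethylating treatment |
| truth-set offsets | ±0.15, 10 positive + 10 negative sets | planted signal for recovery checks |
| per-CpG coverage | Bernoulli(0.5), depth 1 | see below |
| duplicate rate | 5.8 % | realistic library duplication |
| conversion errors | over 1 %, under 2 % | realistic bisulfite chemistry |
| spike-ins | 0.1 % of fragments per class, 20 Cs/read | typical spike-in dosing |

Coverage of 50 % per CpG is roughly tenfold a real single cell (~5 % of
CpGs at 1×). This is the compensating choice forced by scaling the genome
down while keeping the region-set support filter at its absolute
thresholds (min 100 / mean 200 measurements): a realistic coverage on a
toy genome would leave every set unmeasurable. Effects are additive on the
linear probability scale with clamping (a logit option exists) because
methylation differences and residuals live on the fraction scale
throughout.

Each sample draws from an RNG stream keyed by (run seed, CRC32 of sample
id), so per-sample data are independent of group iteration order and the
whole pipeline is bit-reproducible under a fixed seed.

`simulate_regionset_matrix` bypasses the read/call levels and generates the
aggregated matrix directly: value = ref + m·(linear part + offset) + noise.
The linear part is exactly what the per-sample OLS absorbs, so the planted
offsets reappear as residuals; this is the instrument for selection-recovery
and interpolation checks without binomial sampling noise.

### What a green test does not establish

The simulator emulates the *statistical* structure (sparsity, bimodality,
graded region-set effects, duplicates, conversion errors), not real data:
no realistic CpG spatial clustering (islands/shores), no correlated
coverage along fragments at the call level, no cell-cycle or
copy-number-driven coverage bias, no batch effects, and region sets are
disjoint whereas real databases overlap heavily. Passing tests establish
the pipeline computes its definitions correctly and recovers planted
effects at the stated noise levels — not that the method is robust to
everything real scWGBS produces.

## Numerical notes

- OLS via `lstsq` (SVD); rank checked explicitly to name the degenerate
  predictor instead of silently pseudo-inverting.
- Welch–Satterthwaite degrees of freedom via `scipy.stats.ttest_ind`.
- Zero total count in a coverage line is an error (a call with no
  observations is meaningless); a reported percentage disagreeing with the
  counts by > 0.5 warns and the counts win.
- Coverage-file writer is bit-exact (tab-separated, two-decimal percent),
  enabling byte-level determinism checks across pipeline runs.
- Ratio-check odds of 0 or ∞ compare equal only to themselves.
- MDS eigenvalues ≤ ~1e−12 (relative) count as non-positive; degenerate
  all-zero distance matrices embed at the origin.
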