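# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, and what the synthetic data does and does not
emulate. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Study design assumed

The package targets a two-genotype mouse EV experiment: TDP-43\*Q331K
transgenics vs TDP-43\*WT transgenics, sampled at two timepoints (3 and 6
months) in both sexes, with miRNA cargo sequenced from two compartments —
brain-derived EVs (BDEV) and serum EVs — of the same animals. The fully
crossed design gives 2 × 2 × 2 × *n* samples per compartment (24 at the
default of 3 replicates per cell). Genotype is the biological contrast;
timepoint and sex are nuisance factors expected to carry no signal, and
the analysis verifies rather than assumes this.

## Synthetic data

`evmir.synthetic` generates each layer of input with recorded ground
truth.

*Counts.* Per-feature relative abundances are `exp(U(a, b))` normalized
to sum 1; the default natural-log range (0, 7) spans ~3 orders of
magnitude of composition, which reproduces the heavily skewed per-miRNA
totals characteristic of EV small-RNA libraries. Library sizes are
uniform on [0.5 M, 2 M] reads (depth is rarely reported for such studies;
this range is typical of Ion Torrent small-RNA runs and is configurable).
Counts are negative binomial with `var = mu + phi * mu^2` and a default
dispersion `phi = 0.1`, the standard overdispersed model for RNA-seq
counts; `phi -> 0` degenerates to Poisson. A planted log2 fold change
`lfc` is split symmetrically — case means scaled by `2^(+lfc/2)`, control
by `2^(-lfc/2)` — so that the planted effect does not shift the overall
library composition. Timepoint and sex never enter the mean model.

*Reads.* Each read is a reference sequence with optional isomiR-style
edits — up to 2 added or missing bases per end (at most one of add/miss
per end) and up to 2 substitutions — followed by a 3′ adapter, emitted as
DNA with constant Phred quality. The generator refuses edit bounds above
2, matching what the quantifier tolerates. Every edit is recorded, and a
test reconstructs every read from its record.

*What is not emulated:* position-dependent sequencing error, quality-score
realism, UMIs, adapter dimers, cross-mapping families of near-identical
real miRNAs (synthetic references are random and therefore far apart),
and any batch or compartment-specific technical structure. Passing the
recovery tests therefore shows the estimators are correct under the
stated model, not that real libraries are this benign.

## Quantification

Adapter trimming removes everything from the leftmost position where the
adapter — or, at the read's 3′ end, an adapter prefix of at least 8 nt —
matches with a mismatch fraction of at most 0.125.

Alignment is exact enumeration, not a heuristic: a read maps to a mature
sequence if it decomposes as `add5 + core + add3` with the core matching
the mature sequence minus `miss5`/`miss3` terminal bases, all four end
counts at most 2 and core Hamming distance at most 2. Design choices
where the convention is genuinely open:

- *Added terminal bases are unconstrained* and excluded from the mismatch
  count. Genome-aware pipelines template them against the genome; without
  a genome the conservative choice is to treat them as free.
- *Preference order* among candidates: fewest mismatches, then fewest
  total end modifications, then smallest 5′ addition — a canonical-form
  tie-break that makes assignments deterministic.
- *Multi-mapping*: reads tying across references are discarded (counted
  to nothing) by default; `first_by_name` gives a deterministic
  alternative. Discarding avoids double counting.
- *Minimum length 15 nt* after trimming: the shortest mature miRNAs
  (~18 nt) minus the 2 missing bases allowed per end, rounded down.
- Base quality is ignored throughout.

An exhaustive-search oracle (all end-variant tuples, all references) is
kept alongside in the validation module and in the tests; the aligner
agrees with it on 100 % of randomized cases.

## Normalization and QC

TMM follows the published trimmed-mean-of-M-values procedure with its
standard parameters: 30 % two-sided trim on M, 5 % on A, inverse
asymptotic-variance weights `1/v`, `v = (N-y)/(Ny)` summed over the two
samples, reference sample chosen as the one whose upper-quartile CPM is
closest to the cohort mean, factors rescaled to geometric mean 1.
Features with a zero count in either sample of a pair are excluded from
that pair. The implementation is cross-checked in the test suite against
`edgeR::calcNormFactors` (via Rscript) to ~1e-10 relative agreement.

PCA QC operates on feature-centered `log2(CPM + 0.5)` (no variance
scaling; count data on the log scale already have comparable spread). A
sample is flagged when its distance from the score-space centroid, on the
first `k = 2` components, exceeds the median distance by more than 3
robust SDs (1.4826 × MAD). The robust z-score form is used because raw
centroid distances are positive with median far above their spread — a
threshold on the distance itself would flag most of a perfectly
homogeneous cohort. The published analyses this mirrors excluded one
case sample without stating a rule; this rule is the package's declared,
testable stand-in. Flagged samples are dropped before weighting and
testing when `drop_flagged` is set (default).

## Attribute weighting

The five contingency-based models (information gain, gain ratio, gini,
chi-squared, symmetric uncertainty) and the rule score operate on
equal-frequency discretized values (4 bins; duplicate quantile cut points
merged, so heavily tied features occupy fewer bins and a constant feature
one bin). Entropies are in bits. The rule score is per-bin majority-vote
accuracy minus the majority-class baseline, floored at 0. ReliefF runs on
the continuous values: every instance contributes its `k = 10` nearest
hits and misses by Euclidean distance on range-scaled features, with
range-scaled per-feature differences; `k` is truncated (with a warning)
to the smallest class size minus one.

Normalization to [0, 1] is clip-at-zero divided by the column maximum: a
raw weight of 0 ("non-important") always maps to 0, negative Relief
weights (worse than irrelevant) map to 0, and a column with no positive
weight maps to all-0. This keeps each model's scale local to that model —
adding a constant feature cannot change any other feature's normalized
weight. The ensemble is the row sum (range [0, 7]); ranking is by
descending ensemble with lexicographic tie-break.

Open conventions resolved here: weighting runs on `log2(CPM + 0.5)`
(configurable); the signature is a top-*k* cut (default 30) of the full
ranking, which is always emitted.

The confounder scan repeats the ensemble against genotype, timepoint and
sex. Enrichment of a feature set in a ranking is scored by a one-sided
Mann–Whitney test that the set's ranks are *better* than the rest;
one-sided because a genotype-planted feature can legitimately rank
*worse* than average under a nuisance label (its genotype effect inflates
its within-class variance, which depresses Relief weights), and that is
the opposite of confounding.

## Differential expression

- Expression filter: arithmetic mean CPM across all samples ≥ 5
  (inclusive), applied before testing.
- Test: one-way ANOVA on `log2(CPM + 0.5)`; identical to the
  pooled-variance two-sided t-test for two groups. Zero within-group
  variance everywhere yields p = 1 for equal means and the smallest
  positive normal float (with a warning) otherwise.
- Multiple testing: Benjamini–Hochberg step-up, reported as a column.
  The panel gate uses the raw p-value (p < 0.05), not the FDR: with ~11
  samples per group the FDR column of a realistic panel reaches ~0.7, and
  panel definitions in this setting are conventionally raw-p based. This
  is stated on every output.
- Effect size: geometric means within group with a 0.5 pseudocount kept
  inside the log mean; the ratio is taken on the pseudocounted means (so
  it is finite for zero counts), while the reported per-feature geometric
  mean subtracts the pseudocount back. Signed fold change maps ratio `r`
  to `r` (r ≥ 1) or `-1/r`, so |FC| ≥ 1 and the sign is the direction.
- Panel: p < alpha and |FC| ≥ 1.5 *inclusive* by default. The strict
  (">") variant is exposed, but a boundary feature at FC exactly −1.50
  belongs in the panel under the conventions this package reproduces.
- Groups pool both timepoints and sexes (12 vs up to 12 animals), which
  the confounder scan justifies.

Calibration, measured by the acceptance script: on null simulations the
fraction of tested features with p < 0.05 sits inside the 99 % binomial
band around 0.05 (20 × 1000 features), and planted log2 fold changes are
recovered with a mean absolute error of ~0.17 log2 units at 12 samples
per group. Note the per-planting sampling noise at this group size has
SD ≈ 0.2 log2 units, so recovery tolerances are meaningful only as
aggregates, not per feature.

## Panels, intersection, seed sites

Panel intersection is exact string-set intersection of feature names
(after whitespace trimming); suffix variants such as `-486a` vs `-486b`
are distinct features, deliberately — fuzzy matching invites silent
errors. Venn counts partition the union exactly.

Seed handling is first-principles: the seed is mature positions 2–8
(5′→3′), a site is an exact occurrence of its reverse complement on the
UTR plus strand, overlapping occurrences are all reported, and
coordinates are 1-based inclusive. Only plain 7mer sites are called — no
7mer-A1/8mer subtypes, no conservation scoring, no target-database
lookups. Note that published pairing diagrams often print the miRNA
"region" 3′→5′ (the reverse of the seed), so a printed region pairs with
its printed site by position-wise complement; all functions here take
5′→3′ strings. Shared-target counting uses a strict `>` threshold on the
number of distinct miRNAs hitting a UTR.

## Pipeline determinism and problem sizes

Every stage is driven by one integer seed; identical config + seed
reproduce all outputs byte-for-byte, and the resolved-config snapshot
written into each run directory is sufficient to re-run it. Output tables
are TSV with '.' decimals and a header comment naming units and
conventions.

The validation experiments run at the scale of the study they emulate
(24-sample compartments; 300 features for recovery, 1000 for calibration;
20 seeds), which keeps the full suite and the acceptance script each
within tens of seconds on a single CPU.

## Known limitations

- The aligner is exact enumeration over a mature-miRNA reference; there
  is no genome alignment step, so non-templated additions cannot be
  distinguished from genome-templated ones.
- Counts are read counts, not UMI-collapsed molecule counts; with
  UMI-tagged libraries the dispersion parameter absorbs the difference.
- The ensemble is one documented realization of the seven named weighting
  models; it is not bit-compatible with any proprietary implementation of
  the same names.
- The bundled reference panel tables are inputs for convention checks;
  the package cannot re-derive them from raw data, as no raw sequencing
  data are publicly deposited for the study they summarize.
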