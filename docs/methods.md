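# Methods

`evrna` implements a sequence-level analysis of plasma small-RNA sequencing
data, built around the question of whether extracellular-vesicle (EV) RNA
cargo carries Alzheimer's-disease signal — including in "converters", people
whose clinical diagnosis progressed only years after the blood draw. This
note describes the models, the choices behind them, and what the synthetic
cohort does and does not emulate.

## Sequence-level quantification

Small-RNA reads are quantified by *exact sequence*: two reads that differ by
a single nucleotide are two features (isomiRs, tRNA/YRNA fragments and so
on). Reads follow the NEXTFLEX library layout — `4 random nt + insert +
4 random nt + 3' adapter`. Trimming locates the adapter (exact substring
match at the earliest position by default; a mismatch tolerance and a
partial-adapter rule for prefixes of at least 8 nt at the read end are
configurable), removes it and everything 3' of it, then strips the four
randomized bases from each end. Inserts shorter than 15 nt, reads without
an adapter hit, and inserts containing `N` are discarded with per-reason
tallies.

Annotation is an exact-sequence lookup against a provided reference table
(sequence → canonical gene, biotype) rather than a genome alignment. This
preserves the by-sequence semantics the analysis needs, and makes read
processing exactly invertible for testing. Where a sequence could carry
multiple biotype annotations, the resolver applies the standard small-RNA
priority `miRNA > YRNA > tRNA > piRNA > protein_coding > other`.

Gene IDs are generated by suffixing the canonical gene with a 1-based index
ordered by descending total count, ties broken by lexicographic sequence —
so numbering is a pure function of the count matrix, independent of read
order. Samples with ≤ 1,000,000 annotated reads are dropped (strictly "more
than" is required to keep a sample).

## Normalization and differential expression

Size factors are median-of-ratios: for sample *j*,
`s_j = median_g(c_gj / geomean_g(c_g.))` over genes with no zero count in
any sample. The median is taken on the ratio scale; for an even number of
reference genes the two middle ratios are averaged arithmetically.

The differential-expression test is an intentionally simple NB-Wald test.
Genes are filtered on raw counts (> 10 in ≥ 50% of the compared samples);
per gene, group means μ₁, μ₂ are taken on the normalized scale, and a single
dispersion φ is estimated by method of moments from the pooled within-group
variance, `φ = max((s² − μ̄)/μ̄², 0)` with a floor of 1e-8. The Wald statistic
is the log2 fold change `log2((μ₂+0.5)/(μ₁+0.5))` divided by its delta-method
standard error with `Var(c/s) = μ/s + φμ²`; p-values are two-sided normal,
adjusted by step-up Benjamini–Hochberg (NaN excluded from the denominator).
There is **no** dispersion shrinkage, fold-change shrinkage or independent
filtering, so numbers will not match a full shrinkage-based NB pipeline;
the pipeline contract (filter → normalize → per-sequence test → BH) is what
is preserved. Under the synthetic null (φ = 0.2, n = 20/group) the test's
type-I error at p < 0.05 is close to nominal (the acceptance suite asserts
0.03–0.07) and p-values are approximately uniform.

The %CV fraction comparison filters on *normalized* values (> 10 in > 50% of
the pooled samples of both fractions, strict on both thresholds), computes
per-gene `%CV = 100·sd/mean` within each fraction, and compares the two %CV
distributions with a two-sided Welch t-test (unequal variances; the more
conservative choice when one fraction is planted noisier). Detection overlap
counts sequences with any nonzero count per fraction, matched by sequence so
that fraction-specific gene numbering cannot desynchronize the comparison.

## Three-loop elastic net

Classification between two groups uses penalized logistic regression with
the elastic-net penalty, objective
`(1/n)Σ logloss + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)`, mixing parameter α = 0.5 by
default (exposed everywhere). Candidate features are the sequences with
unadjusted DE p < 0.05 between the two groups. Feature columns are
median-ratio normalized, log2(x+1)-transformed and standardized; penalized
fits are scale-sensitive, so the transformation is part of the model and is
stored with it.

1. **Penalty tuning.** Each iteration draws a random 80/20 train/test split
   (single-class training draws are redrawn, bounded), runs 3-fold
   cross-validation over a 15-point log-spaced penalty path on the training
   part, refits at the CV-accuracy-optimal penalty, and scores the held-out
   20% at the 0.5 probability cutoff. The penalty from the
   highest-accuracy iteration wins; ties go to the first maximum.
2. **Feature selection.** The same resampling at the fixed penalty; the
   nonzero-coefficient features of the best-accuracy iteration are kept.
3. **Performance.** Resampling with penalty and feature set fixed; mean ±
   sd of held-out accuracy and trapezoidal ROC AUC are reported
   (single-class test splits contribute no AUC and are counted). A single
   AUC definition — test-split ROC — is used in all loops.

The best model is refit on all comparison samples and applied to every
sample for the waterfall display (samples ordered by ascending class
probability). Held-out samples — converters — are projected through the
fitted model; their size factors are computed against the training
pseudo-reference (per-gene log geometric means of training counts), so
projection never touches training-time statistics it shouldn't.

Two properties of this procedure deserve flagging. First, feature
preselection uses *all* samples of the comparison, as do the best-iteration
choices in loops 1–2; held-out accuracies are therefore optimistic
(selection bias). A label permutation applied upstream of these data-driven
selection steps yields accuracies far above chance for exactly this reason
— permuting before preselection gives near-perfect "held-out" accuracy, and
even permuting between preselection and the loops leaves a bias of roughly
0.1–0.2. The chance-level control is therefore defined at the level where
chance is the right expectation: labels permuted against the *fixed* best
model (penalty and feature set held), where the resampled performance loop
scores near 0.5. Second, the resampled "best" split accuracy is a maximum
statistic and is reported separately from the loop-3 mean ± sd.

Defaults: 1000 iterations per loop (the study-scale setting); tests and the
acceptance script run 10–200 iterations, which the stability checks show is
sufficient for the quantities asserted.

## Logistic-regression benchmark and conversion trends

The comparison model is an unpenalized binomial GLM on the top 10 DE
sequences, selected either by ascending adjusted p-value or by descending
|log2FC| (both implemented; the criterion is a required argument; ties break
on the other criterion, then gene ID). It is evaluated over repeated random
80/20 splits (100 by default) with the same accuracy/AUC definitions as the
elastic net. Features are standardized internally for numerical stability;
perfect-separation fits are bounded by the iteration cap and counted.

Time-to-conversion trends are per-gene ordinary least squares of normalized
log2 expression on `x = −years_to_conversion` (x = −4 means conversion came
4 years after the draw), restricted to converter samples (at least 3
required). The slope is in log2 normalized-expression units per year; its
p-value is the two-sided t-test on the OLS slope, and genes with R² ≥ 0.66
and p < 0.05 are flagged. Whether to use raw or normalized expression here
is an open choice; normalized log2 is used because the planted trends are
multiplicative and library sizes vary.

## Cohort curation

Postmortem pathology does not always match clinical diagnosis. Curation
applies, in order: (1) never-converting controls with postmortem AD
pathology are excluded; (2) controls with confirmed PART (primary
age-related tauopathy) are excluded from disease comparisons but retained to
train the PART model; (3) unautopsied controls that the PART model places at
≥ 50% PART probability (inclusive) are excluded; (4) never-converting MCI
with postmortem DLB are excluded; (5) FTD/vascular pathology in
non-converters is excluded by default (configurable, since the right call is
cohort-dependent); (6) participants whose diagnosis progressed after the
draw form the converter groups C_to_MCI, C_to_AD, MCI_to_AD; (7) everyone
else keeps the diagnosis at draw. Pathology exclusions deliberately apply
only to non-converters: an autopsy confirming a converter's destination
diagnosis validates the conversion rather than disqualifying the sample.
The PART model itself is the full three-loop elastic net on
autopsy-confirmed normal vs PART controls.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults describe a cohort of
the scale the pipeline targets (about 110 EV samples across control/MCI/AD
plus 9 + 6 + 6 converters, with EV-depleted counterparts for a subset, and
library sizes around 2 million reads). What it emulates:

- **Reference**: canonical genes per biotype with isomiR families (1 +
  Poisson-distributed extra members derived by substitution, end-trimming
  or 3' extension), sequences 15–45 nt, globally unique.
- **Counts**: gamma-Poisson (negative binomial, `Var = μ + φμ²`, φ = 0.2 by
  default) around log-normal baseline abundances (log-sd 1.8 — a few
  dominant transcripts carry most reads, as in plasma) scaled by log-normal
  library-size factors (log-sd 0.4).
- **Group effects**: planted log2 fold changes keyed to clinical groups, to
  converter groups (converter-unique signatures), or to *latent pathology*
  (e.g. PART). Converters express a configurable fraction `scale` of the
  destination group's effect ((1−scale) of the origin's for MCI→AD), which
  makes the projection analyses testable and monotone by construction.
- **Trends**: selected rows gain `slope × (−years_to_conversion)` log2
  units in converter samples.
- **Pathology**: every sample draws a latent pathology from
  group-conditional rates; it is observed (as `postmortem_dx`) only with
  the autopsy probability, otherwise recorded as `unknown`. The latent
  column is simulation ground truth for testing the PART flagging; the
  analysis code never reads it.
- **EV-depleted fraction**: a shared random subset of genes (default 30%)
  is zeroed, and per-gene multiplicative log-normal noise is added with
  variance chosen so the per-gene %CV is multiplied by approximately the
  design factor (default 2). The closed form: for target factor c and base
  squared CV `c₀² = 1/μ + φ`, the multiplier variance is
  `v = c₀²(c²−1)/(1+φ)`.
- **Covariates**: DRS and MMSE from group-conditional normals clipped to
  their valid ranges (centered near the published cutoffs: DRS 136 separates
  control from impairment, 124 separates MCI from AD; MMSE bands 20–26 mild,
  10–19 moderate); ApoE genotypes with the E3/E4- and E4/E4-enriched AD
  profile; these are cosmetic, carrying no expression signal.

Randomness is split into independent child streams (reference, metadata,
counts, reads) from one master seed, so artifacts can be regenerated in
isolation and everything is bit-reproducible. Read simulation emits one
read per count unit with a constant quality string, making read processing
exactly invertible — the identity round-trip is asserted in the tests.

Not emulated: sequencing error, quality-score variation, adapter dimers,
UMI structure, alignment multi-mapping ambiguity, batch effects, and any
correlation structure between genes beyond the shared library factor.
Passing tests therefore demonstrate the *procedures* behave as specified on
data with the assumed generative structure, not that real plasma data meet
those assumptions.

Effect sizes are not dictated by any published cohort; the defaults used in
tests (|log2FC| = 2 disease effects, 2.5 for PART, 0.4 log2-units/year
trends) are chosen to be comfortably detectable at the simulated sample
sizes, so that test failures indicate implementation defects rather than
power shortfalls. The helper `choose_expressed_rows` plants effects on genes
that pass the expression filter under the effect-free design (the baseline
abundance draw depends only on the seed), so planted-recovery rates are
measured over genes the analysis actually tests.

## Problem sizes in tests and the acceptance script

Simulations are scaled to what the checks need: 1000 genes × 20 samples for
the read-processing round trip (50k reads/sample), 2000 genes × 40 samples
for DE calibration, ~5000 genes with 10 planted features for elastic-net
recovery at 200 iterations per loop, 20 replicate seeds × 10 converters for
projection monotonicity, and 100 replicate panels of 9 converters for trend
recovery. These sizes give stable Monte-Carlo estimates for the asserted
tolerances while keeping the suite fast.

## Known limitations

- The NB-Wald test is anti-conservative for very low counts and has no
  shrinkage; it is calibrated at the simulated depths, not guaranteed so at
  shallow ones.
- The elastic-net procedure's resampled accuracies are optimistic by
  construction (preselection and best-iteration choice see all samples);
  the projection of truly held-out converters is the honest read-out.
- Exact-match annotation cannot place reads with sequencing errors; on real
  data it would undercount relative to alignment-based quantification.
- Single blood draw per subject: trends across converters are
  cross-sectional, not longitudinal within-person slopes.
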