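# evrna

Sequence-level analysis of small RNAs in plasma extracellular vesicles (EVs),
aimed at studies that ask whether circulating EV-RNA cargo can diagnose
Alzheimer's disease (AD) and flag *preclinical converters* — participants who
were cognitively normal (or MCI) at the blood draw and progressed to MCI or
AD only years later. It is a library for bioinformaticians and biostatisticians
working with small RNA-seq of biofluids, with a thin CLI for running the whole
workflow from a shell.

## What it does

Every distinct small-RNA sequence (isomiR, tRNA/YRNA/piRNA fragment,
protein-coding fragment) is its own feature: sequences differing by one
nucleotide are counted separately, and gene IDs are generated as
`canonical-gene-k` with k ranked by abundance.

- **Read processing** — NEXTFLEX-style trimming (3' adapter + 4 random nt on
  each end of the insert; inserts < 15 nt discarded), exact-sequence
  collapsing against an annotated reference, biotype priority
  `miRNA > YRNA > tRNA > piRNA > protein_coding > other`, and a
  \>1M-annotated-reads sample QC gate.
- **Expression statistics** — median-of-ratios size factors; an NB-Wald
  differential-expression test (`Var = μ + φμ²`, moment dispersion,
  Benjamini–Hochberg adjustment); per-gene %CV comparison between EV and
  EV-depleted fractions (Welch t-test); detection overlap; DE-set
  concordance (shared significant sequences and fold-change sign agreement).
- **Three-loop elastic net** — penalty tuned, features selected, and
  performance estimated over repeated random 80/20 splits on DE-preselected
  sequences (`(1/n)Σ logloss + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)`, α = 0.5 default);
  the best model scores all samples (waterfall) and projects held-out
  converter samples.
- **Benchmark & trends** — unpenalized binomial GLM on the top-10 DE
  sequences over 100 repeated splits; per-gene OLS of expression on
  `x = −years_to_conversion` with an R² ≥ 0.66, p < 0.05 flag.
- **Cohort curation** — reconciles clinical diagnosis with postmortem
  pathology: excludes controls with AD pathology, confirmed-PART controls,
  model-flagged suspected-PART controls (≥ 50% probability), MCI with Lewy
  body disease; assigns converter groups.
- **Synthetic cohort generator** — fully seeded negative-binomial cohorts
  with isomiR families, planted group/pathology effects, scaled converter
  signal, time-to-conversion trends, EV-depleted dropout and %CV inflation,
  and latent pathology observed only at autopsy. This is tested, first-class
  code: it defines the conditions under which every statistical claim in the
  test suite is checked.

## Worked example

`examples/03_elastic_net_and_projection.py` plants ten |log2FC| = 2 AD
effects in a 36-sample cohort plus six control→AD converters carrying the
full disease effect, trains the three-loop elastic net on non-converters,
and projects the converters:

```
model: 8 sequences at lambda = 0.1941
held-out accuracy 1.000 +/- 0.000, AUC 1.000 (mean +/- sd over 100 splits)

converter projection (6/6 called AD):
               probability assigned_class
sample_id
C_to_AD-05-EV        0.735             AD
C_to_AD-01-EV        0.756             AD
C_to_AD-04-EV        0.821             AD
C_to_AD-03-EV        0.822             AD
C_to_AD-06-EV        0.865             AD
C_to_AD-02-EV        0.912             AD
probability > 0.5 means the preclinical sample already looks like AD
```

The model recovers the planted sequences, classifies held-out splits nearly
perfectly, and places every preclinical converter on the disease side —
the blood draw "knew" years before the diagnosis did. The other examples
cover simulation + read-processing round trip (`01`), differential
expression (`02`), pathology-informed curation with PART flagging (`04`),
and fraction comparison + conversion trends (`05`).

The full workflow also runs from a shell:

```bash
evrna run-all --outdir run1 --seed 7 --iters 200   # simulate → … → trends
evrna de --counts counts.tsv --lookup lookup.tsv --metadata meta.tsv \
         --group-a control --group-b AD --out de.tsv
```

`run-all` writes per-stage TSVs plus `run_report.json`; identical config and
seed give identical reports.

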