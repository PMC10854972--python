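"""EV vs EV-depleted variability, detection overlap, and conversion trends.

Two analyses on one cohort: (1) the EV-depleted fraction is simulated with a
2x per-gene %CV inflation and 30% gene dropout, and the Welch test on %CV
distributions detects the difference; (2) a sequence whose log2 expression
rises by 0.4 per year as conversion approaches is recovered by per-gene OLS
against x = -years_to_conversion.
"""

import numpy as np

from evrna import SimulationDesign, detection_overlap, normalize, \
    percent_cv_comparison, simulate_cohort, simulate_reference, size_factors, \
    time_to_conversion_regression
from evrna.simulate import TrendGene

base = SimulationDesign(
    seed=41,
    n_per_group={"control": 20, "C_to_MCI": 9},
    n_genes_per_biotype={"miRNA": 200, "YRNA": 60, "tRNA": 60, "piRNA": 60,
                         "protein_coding": 60, "other": 60},
    isomir_mean_family_size=1.0,
    library_size_mean=200_000,
    n_depleted_per_group={"control": 16},
    autopsy_rate=0.0,
    depleted_fraction_cv_inflation=2.0,
    depleted_dropout_rate=0.3,
)
reference = simulate_reference(base)
_, probe = simulate_cohort(base, reference)
top_seq = probe.annotation.loc[probe.counts.sum(axis=1).idxmax(), "sequence"]
trend_row = next(i for i, e in enumerate(reference) if e.sequence == top_seq)
design = SimulationDesign(**{**vars(base),
                             "trend_genes": [TrendGene(trend_row, 0.4)]})
metadata, matrix = simulate_cohort(design, reference)

ev = matrix.subset_samples(metadata.index[metadata["fraction"] == "EV"])
dep = matrix.subset_samples(metadata.index[metadata["fraction"] == "depleted"])
cv = percent_cv_comparison(normalize(ev.counts), normalize(dep.counts))
print(f"%CV over {cv.n_genes} jointly expressed genes: "
      f"EV median {cv.cv_a.median():.1f}, depleted median {cv.cv_b.median():.1f}, "
      f"Welch p = {cv.p:.2e}")
print("(the depleted fraction is built noisier: RNP/lipoprotein-bound RNA)")

ov = detection_overlap(ev, dep)
print(f"detection: {ov.n_both} sequences in both fractions, "
      f"{ov.n_a_only} EV-only, {ov.n_b_only} depleted-only")

converters = list(metadata.index[metadata["group"] == "C_to_MCI"])
sf = size_factors(ev.counts)
logq = np.log2(ev.counts / sf + 1.0)
trends = time_to_conversion_regression(
    logq[converters], metadata.loc[converters, "years_to_conversion"])
lut = {s: g for g, s in matrix.annotation["sequence"].items()}
hit = trends.loc[lut[top_seq]]
print(f"\nplanted trend gene {lut[top_seq]}: slope {hit['slope']:.3f} "
      f"log2-units/year (planted 0.4), R^2 = {hit['r2']:.2f}, p = {hit['p']:.3g}")
print(f"{int(trends['flagged'].sum())} of {len(trends)} sequences flagged at "
      f"R^2 >= 0.66, p < 0.05")
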