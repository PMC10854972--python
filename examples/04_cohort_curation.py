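"""Pathology-informed curation: excluding suspected-PART controls.

Some clinically normal controls carry tau pathology (PART) or even AD
pathology only visible at autopsy. This example plants a PART expression
signature, trains an elastic-net model on autopsy-confirmed normal vs PART
controls, flags unautopsied controls the model places on the PART side at
>= 50% probability, and applies the full rule set to produce final analysis
groups.
"""

from evrna import SimulationDesign, apply_curation_rules, build_part_model, \
    flag_suspected_part, simulate_cohort, simulate_reference
from evrna.curation import summarize_curation
from evrna.simulate import PlantedEffect, choose_expressed_rows

base = SimulationDesign(
    seed=31,
    n_per_group={"control": 36, "MCI": 10, "AD": 10},
    n_genes_per_biotype={"miRNA": 150, "YRNA": 40, "tRNA": 40, "piRNA": 40,
                         "protein_coding": 40, "other": 40},
    isomir_mean_family_size=1.0,
    library_size_mean=150_000,
    n_depleted_per_group={},
    autopsy_rate=0.4,
    pathology_mislabel_rates={"control_PART": 0.35, "control_AD": 0.1,
                              "MCI_DLB": 0.2, "MCI_other": 0.05,
                              "AD_other": 0.05},
)
reference = simulate_reference(base)
rows = choose_expressed_rows(base, reference)[:8]
design = SimulationDesign(**{**vars(base),
                             "planted_effects": [PlantedEffect(rows, "PART", 2.5)]})
metadata, matrix = simulate_cohort(design, reference)

ctl = metadata[(metadata["dx_at_draw"] == "control")
               & (metadata["converts_to"] == "none")]
print("observed pathology in controls:",
      ctl["postmortem_dx"].value_counts().to_dict())

model, perf = build_part_model(matrix.counts, metadata, n_iter=60, seed=5)
print(f"PART model: {len(model.features)} sequences, "
      f"best training accuracy {perf.best_accuracy:.2f}")

flagged = flag_suspected_part(model, matrix.counts, metadata)
truth = set(ctl.index[(ctl["postmortem_dx"] == "unknown")
                      & (ctl["latent_pathology"] == "PART")])
print(f"flagged {len(flagged)} unautopsied controls as suspected PART "
      f"({len(truth & set(flagged))} of {len(truth)} latent-PART controls)")

curated = apply_curation_rules(metadata, flagged)
report = summarize_curation(curated, flagged)
print("final groups:", report.group_sizes)
print("exclusions by reason:", report.exclusions_by_reason)
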