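import pandas as pd
import pytest

from evrna.containers import AnnotatedReference, ReferenceEntry
from evrna.simulate import (
    PlantedEffect,
    SimulationDesign,
    choose_expressed_rows,
    simulate_cohort,
    simulate_reference,
)


@pytest.fixture(scope="session")
def tiny_reference() -> AnnotatedReference:
    """Hand-built reference with one isomiR family and every biotype."""
    return AnnotatedReference(
        [
            ReferenceEntry("ACGTACGTACGTACGTACGT", "miR-a", "miRNA"),
            ReferenceEntry("ACGTACGTACGTACGTACGA", "miR-a", "miRNA"),  # 1-nt isomiR
            ReferenceEntry("TTTTCCCCGGGGAAAATTTTCC", "miR-b", "miRNA"),
            ReferenceEntry("GGGGAAAATTTTCCCCGGGGAAAA", "RNY-1", "YRNA"),
            ReferenceEntry("CCCCAAAAGGGGTTTTCCCCAAAAGGGG", "tRF-1", "tRNA"),
            ReferenceEntry("AACCGGTTAACCGGTTAACCGGTTAA", "piR-1", "piRNA"),
            ReferenceEntry("ATATATCGCGCGATATATCG", "PC-1", "protein_coding"),
            ReferenceEntry("GCGCGCATATATGCGCGCAT", "misc-1", "other"),
        ]
    )


def small_design(seed: int = 0, **overrides) -> SimulationDesign:
    """A fast, effect-free design used as the base for most tests."""
    base = dict(
        n_per_group={"control": 12, "AD": 12},
        n_genes_per_biotype={
            "miRNA": 80,
            "YRNA": 20,
            "tRNA": 20,
            "piRNA": 20,
            "protein_coding": 20,
            "other": 20,
        },
        isomir_mean_family_size=1.0,
        library_size_mean=150_000,
        gene_dispersion=0.2,
        n_depleted_per_group={},
        autopsy_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationDesign(**base)


@pytest.fixture(scope="session")
def disease_cohort():
    """A moderate cohort with planted AD effects on well-expressed genes.

    Returns (design, reference, metadata, matrix, planted_row_indices).
    """
    d0 = small_design(
        seed=101,
        n_per_group={"control": 16, "AD": 16, "C_to_AD": 8},
        n_genes_per_biotype={
            "miRNA": 120,
            "YRNA": 30,
            "tRNA": 30,
            "piRNA": 25,
            "protein_coding": 25,
            "other": 20,
        },
        converter_effect_scale=1.0,
    )
    ref = simulate_reference(d0)
    rows = choose_expressed_rows(d0, ref)
    planted = rows[:10]
    design = SimulationDesign(
        **{
            **vars(d0),
            "planted_effects": [
                PlantedEffect(planted[:5], "AD", 2.0),
                PlantedEffect(planted[5:], "AD", -2.0),
            ],
        }
    )
    metadata, matrix = simulate_cohort(design, ref)
    return design, ref, metadata, matrix, planted


def seq_to_gene_id(matrix, reference, row_indices):
    """Map reference row indices to the gene IDs they received in a matrix."""
    lut = {s: g for g, s in matrix.annotation["sequence"].items()}
    return [lut[reference.entries[i].sequence] for i in row_indices
            if reference.entries[i].sequence in lut]
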