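"""Core data containers shared across the pipeline.

The analysis is *sequence-level*: every distinct small-RNA sequence (isomiR,
tRNA fragment, YRNA fragment, ...) is its own feature, even when two sequences
differ by a single nucleotide. Rows therefore carry both a generated gene ID
(``canonical_gene-<k>``) and the underlying sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Closed biotype vocabulary, ordered by annotation priority (multi-mapping
#: reads are assigned the highest-priority biotype among their candidates).
BIOTYPES = ("miRNA", "YRNA", "tRNA", "piRNA", "protein_coding", "other")
BIOTYPE_PRIORITY = {b: i for i, b in enumerate(BIOTYPES)}

#: Clinical groups at blood draw plus converter groups assigned during curation.
STATIC_GROUPS = ("control", "MCI", "AD")
CONVERTER_GROUPS = ("C_to_MCI", "C_to_AD", "MCI_to_AD")

#: Postmortem pathology vocabulary.
PATHOLOGIES = ("normal", "PART", "AD", "DLB", "FTD", "vascular", "unknown")

METADATA_COLUMNS = [
    "sample_id",
    "fraction",
    "dx_at_draw",
    "postmortem_dx",
    "converts_to",
    "years_to_conversion",
    "DRS",
    "MMSE",
    "apoe",
    "sex",
    "age",
]


@dataclass(frozen=True)
class ReferenceEntry:
    sequence: str
    canonical_gene: str
    biotype: str


class AnnotatedReference:
    """Exact-sequence annotation table: sequence -> (canonical gene, biotype).

    Stands in for a genome/transcriptome alignment step: quantification is by
    exact sequence identity, which preserves isomiR resolution.
    """

    def __init__(self, entries: Iterable[ReferenceEntry]):
        self.entries: list[ReferenceEntry] = list(entries)
        seqs = [e.sequence for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("reference sequences must be unique")
        for e in self.entries:
            if e.biotype not in BIOTYPES:
                raise ValueError(f"unknown biotype {e.biotype!r}")
            if not e.sequence or set(e.sequence) - set("ACGT"):
                raise ValueError(f"invalid sequence {e.sequence!r}")
        self.by_sequence: dict[str, ReferenceEntry] = {
            e.sequence: e for e in self.entries
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [e.sequence for e in self.entries],
                "canonical_gene": [e.canonical_gene for e in self.entries],
                "biotype": [e.biotype for e in self.entries],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotatedReference":
        df = pd.read_csv(path, sep="\t")
        return cls(
            ReferenceEntry(r.sequence, r.canonical_gene, r.biotype)
            for r in df.itertuples()
        )


@dataclass
class SequenceCountMatrix:
    """Integer counts with one row per distinct sequence.

    ``counts`` is indexed by generated gene IDs; ``annotation`` (same index)
    carries sequence, canonical gene and biotype per row.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.annotation.index):
            raise ValueError("counts and annotation must share an index")
        if self.counts.index.has_duplicates:
            raise ValueError("gene IDs must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sequences(self) -> pd.Series:
        return self.annotation["sequence"]

    @property
    def biotypes(self) -> pd.Series:
        return self.annotation["biotype"]

    def subset_samples(self, samples: Iterable[str]) -> "SequenceCountMatrix":
        return SequenceCountMatrix(self.counts[list(samples)], self.annotation)

    def to_tsv(self, counts_path: str | Path, lookup_path: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        if lookup_path is not None:
            lk = self.annotation.copy()
            lk.index.name = "gene_id"
            lk.to_csv(lookup_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, lookup_path: str | Path) -> "SequenceCountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        lookup = pd.read_csv(lookup_path, sep="\t", index_col="gene_id")
        return cls(counts, lookup.loc[counts.index])


def build_count_matrix(
    seq_counts: Mapping[str, Mapping[str, int]] | pd.DataFrame,
    reference: AnnotatedReference,
) -> SequenceCountMatrix:
    """Assemble a :class:`SequenceCountMatrix` from per-sequence tallies.

    ``seq_counts``: mapping sample -> {sequence: count} (or an equivalent
    DataFrame indexed by sequence). Only sequences present in ``reference``
    may appear. Gene IDs are generated by suffixing the canonical gene with a
    1-based rank ordered by descending total count (ties broken by
    lexicographic sequence), so the numbering is deterministic for a given
    matrix regardless of input order.
    """
    if isinstance(seq_counts, pd.DataFrame):
        table = seq_counts.copy()
    else:
        table = pd.DataFrame(seq_counts).fillna(0)
        table = table[list(seq_counts.keys())]
    table = table.astype(np.int64)
    table.index.name = "sequence"

    missing = [s for s in table.index if s not in reference.by_sequence]
    if missing:
        raise KeyError(f"{len(missing)} sequences absent from reference, e.g. {missing[0]!r}")

    totals = table.sum(axis=1)
    order = sorted(table.index, key=lambda s: (-totals[s], s))
    table = table.loc[order]

    canon = [reference.by_sequence[s].canonical_gene for s in table.index]
    biot = [reference.by_sequence[s].biotype for s in table.index]
    rank: dict[str, int] = {}
    gene_ids = []
    for g in canon:
        rank[g] = rank.get(g, 0) + 1
        gene_ids.append(f"{g}-{rank[g]}")

    annotation = pd.DataFrame(
        {"sequence": table.index, "canonical_gene": canon, "biotype": biot},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    counts = table.set_index(pd.Index(gene_ids, name="gene_id"))
    return SequenceCountMatrix(counts, annotation)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata table and return it indexed by sample_id."""
    df = metadata.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id", drop=False)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = df.loc[(df["converts_to"] == "none") & (df["years_to_conversion"] > 0)]
    if len(bad):
        raise ValueError(
            f"non-converters with years_to_conversion > 0: {list(bad.index[:3])}"
        )
    if ((df["MMSE"] < 0) | (df["MMSE"] > 30)).any():
        raise ValueError("MMSE out of range [0, 30]")
    return df
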