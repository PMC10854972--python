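"""Raw-read processing: adapter/4N trimming, exact-sequence collapsing,
biotype annotation, and per-sample QC.

Libraries are assumed to follow the NEXTFLEX small-RNA design: the sequenced
read is ``4 random nt + insert + 4 random nt + 3' adapter (+ downstream)``.
Trimming locates the adapter, strips it and everything 3' of it, then removes
the four randomized bases from each end. Inserts shorter than 15 nt after
trimming are discarded. Quantification is by exact sequence match against an
:class:`~evrna.containers.AnnotatedReference`; distinct sequences are kept as
distinct features even when they differ by a single nucleotide.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .containers import (
    BIOTYPE_PRIORITY,
    BIOTYPES,
    AnnotatedReference,
    SequenceCountMatrix,
    build_count_matrix,
)

#: 3' adapter of the NEXTFLEX small RNA-seq v2 kit (TruSeq-compatible).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

KEPT = "kept"
NO_ADAPTER = "no_adapter"
TOO_SHORT = "too_short"
AMBIGUOUS = "ambiguous_base"


@dataclass(frozen=True)
class TrimResult:
    sequence: str | None
    reason: str

    @property
    def kept(self) -> bool:
        return self.reason == KEPT


def _find_adapter(raw: str, adapter: str, max_mismatches: int, min_partial: int) -> int:
    """Earliest adapter start, or -1.

    With ``max_mismatches == 0`` a plain substring search is used. A partial
    adapter prefix of at least ``min_partial`` nt at the very end of the read
    also counts (the adapter may be truncated by the read length).
    """
    if max_mismatches == 0:
        pos = raw.find(adapter)
        if pos != -1:
            return pos
    else:
        la = len(adapter)
        for pos in range(len(raw) - la + 1):
            mm = sum(a != b for a, b in zip(raw[pos : pos + la], adapter))
            if mm <= max_mismatches:
                return pos
    # partial adapter running off the 3' end
    la = len(adapter)
    for k in range(la - 1, min_partial - 1, -1):
        if len(raw) >= k and raw.endswith(adapter[:k]):
            return len(raw) - k
    return -1


def trim_read(
    raw: str,
    adapter: str = DEFAULT_ADAPTER,
    n_random: int = 4,
    min_len: int = 15,
    max_mismatches: int = 0,
    min_partial: int = 8,
) -> TrimResult:
    """Trim one read; returns the insert or a discard reason."""
    if set(adapter) - set("ACGT"):
        raise ValueError("adapter must be over {A,C,G,T}")
    raw = raw.upper()
    pos = _find_adapter(raw, adapter, max_mismatches, min_partial)
    if pos == -1:
        return TrimResult(None, NO_ADAPTER)
    insert = raw[:pos]
    # strip the randomized bases ligated to both ends of the insert
    insert = insert[n_random : len(insert) - n_random]
    if len(insert) < min_len:
        return TrimResult(None, TOO_SHORT)
    if "N" in insert:
        return TrimResult(None, AMBIGUOUS)
    return TrimResult(insert, KEPT)


def assign_biotype_priority(candidates: Iterable[str]) -> str:
    """Resolve multi-annotation by priority miRNA > YRNA > tRNA > piRNA >
    protein_coding > other."""
    cand = set(candidates)
    if not cand:
        raise ValueError("empty candidate set")
    unknown = cand - set(BIOTYPES)
    if unknown:
        raise ValueError(f"unknown biotype(s): {sorted(unknown)}")
    return min(cand, key=BIOTYPE_PRIORITY.__getitem__)


def collapse_and_annotate(
    reads_by_sample: Mapping[str, Iterable[str]],
    reference: AnnotatedReference,
) -> tuple[SequenceCountMatrix, pd.DataFrame, dict[str, int]]:
    """Collapse trimmed reads to per-sequence counts and annotate them.

    Returns ``(matrix, lookup, unannotated)`` where ``lookup`` maps each
    generated gene ID to its sequence/canonical gene/biotype and
    ``unannotated`` tallies, per sample, reads whose sequence is absent from
    the reference (excluded from the matrix).
    """
    if len(reference) == 0:
        raise ValueError("empty reference")
    known = reference.by_sequence
    per_sample: dict[str, Counter] = {}
    unannotated: dict[str, int] = {}
    for sample, reads in reads_by_sample.items():
        tally: Counter = Counter()
        miss = 0
        for seq in reads:
            if seq in known:
                tally[seq] += 1
            else:
                miss += 1
        per_sample[sample] = tally
        unannotated[sample] = miss

    all_seqs = sorted({s for t in per_sample.values() for s in t})
    table = pd.DataFrame(
        {sample: [per_sample[sample].get(s, 0) for s in all_seqs] for sample in per_sample},
        index=pd.Index(all_seqs, name="sequence"),
    )
    matrix = build_count_matrix(table, reference)
    lookup = matrix.annotation.copy()
    return matrix, lookup, unannotated


def qc_filter_samples(
    matrix: SequenceCountMatrix, min_mapped: int = 1_000_000
) -> tuple[SequenceCountMatrix, list[str]]:
    """Drop samples without *more than* ``min_mapped`` annotated reads."""
    sums = matrix.counts.sum(axis=0)
    kept = [s for s in matrix.sample_ids if sums[s] > min_mapped]
    excluded = [s for s in matrix.sample_ids if sums[s] <= min_mapped]
    return matrix.subset_samples(kept), excluded


def biotype_composition(
    matrix: SequenceCountMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample read fraction per biotype and per-sample transcript
    diversity (number of detected unique sequences) per biotype."""
    if matrix.counts.empty:
        raise ValueError("empty matrix")
    bt = matrix.biotypes
    totals = matrix.counts.groupby(bt).sum()
    colsums = totals.sum(axis=0)
    fractions = (totals / colsums).T.reindex(columns=list(BIOTYPES), fill_value=0.0)
    diversity = (matrix.counts > 0).groupby(bt).sum().T.reindex(
        columns=list(BIOTYPES), fill_value=0
    )
    return fractions, diversity


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_sequences(path: str | Path) -> list[str]:
    with _open_maybe_gz(Path(path)) as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]


def count_fastq_dir(
    fastq_dir: str | Path,
    reference: AnnotatedReference,
    adapter: str = DEFAULT_ADAPTER,
    n_random: int = 4,
    min_len: int = 15,
    max_mismatches: int = 0,
    min_mapped: int = 1_000_000,
) -> tuple[SequenceCountMatrix, dict]:
    """Full read-processing stage for a directory of per-sample FASTQ files.

    Sample names are file stems (``X.fastq`` / ``X.fastq.gz`` -> ``X``).
    Returns the QC-filtered matrix and a per-sample report of
    retained/discarded/unannotated tallies.
    """
    fastq_dir = Path(fastq_dir)
    files = sorted(
        p for p in fastq_dir.iterdir() if p.name.endswith((".fastq", ".fastq.gz", ".fq", ".fq.gz"))
    )
    if not files:
        raise FileNotFoundError(f"no FASTQ files in {fastq_dir}")
    trimmed: dict[str, list[str]] = {}
    report: dict = {"samples": {}}
    for path in files:
        sample = path.name.split(".")[0]
        kept: list[str] = []
        reasons = Counter()
        for raw in read_fastq_sequences(path):
            res = trim_read(raw, adapter, n_random, min_len, max_mismatches)
            reasons[res.reason] += 1
            if res.kept:
                kept.append(res.sequence)
        trimmed[sample] = kept
        report["samples"][sample] = {
            "total_reads": sum(reasons.values()),
            "retained": reasons[KEPT],
            "discarded_no_adapter": reasons[NO_ADAPTER],
            "discarded_too_short": reasons[TOO_SHORT],
            "discarded_ambiguous": reasons[AMBIGUOUS],
        }
    matrix, _, unannotated = collapse_and_annotate(trimmed, reference)
    for sample, miss in unannotated.items():
        rep = report["samples"][sample]
        rep["unannotated"] = miss
        rep["annotated"] = rep["retained"] - miss
    matrix, excluded = qc_filter_samples(matrix, min_mapped)
    report["qc_excluded_samples"] = excluded
    report["min_mapped"] = min_mapped
    return matrix, report
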