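"""Synthetic plasma small-RNA cohort generator.

Emulates the statistical structure the downstream analysis assumes for a
plasma EV small-RNA study of Alzheimer's disease:

* an annotated sequence reference with isomiR families (several distinct
  sequences per canonical gene, differing by >= 1 nt);
* negative-binomial counts with log-normal abundance skew (a handful of
  dominant transcripts) and library-size variation;
* planted group effects (control / MCI / AD) with configurable log2
  fold changes, including effects keyed to latent postmortem pathology
  (e.g. PART) rather than clinical diagnosis;
* converter samples (control->MCI, control->AD, MCI->AD) expressing a
  configurable fraction of the full disease effect, plus per-gene linear
  trends in time-to-conversion;
* an EV-depleted fraction with planted gene dropout and inflated per-gene
  coefficient of variation;
* clinical covariates (DRS, MMSE, ApoE, sex, age) drawn from
  group-conditional distributions.

Everything is driven by a single :class:`SimulationDesign` and a master seed;
metadata, counts and reads use independent child RNG streams so each artifact
can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    BIOTYPES,
    CONVERTER_GROUPS,
    PATHOLOGIES,
    STATIC_GROUPS,
    AnnotatedReference,
    ReferenceEntry,
    SequenceCountMatrix,
    build_count_matrix,
)
from .reads import DEFAULT_ADAPTER

_NT = np.array(list("ACGT"))

#: Canonical-gene name prefix per biotype (clearly synthetic names).
GENE_PREFIX = {
    "miRNA": "miR-sim",
    "YRNA": "RNY-sim",
    "tRNA": "tRF-sim",
    "piRNA": "piR-sim",
    "protein_coding": "PC-sim",
    "other": "misc-sim",
}

#: Insert length range per biotype (nt); all within the 15-45 nt window the
#: size selection of a small-RNA library retains.
LENGTH_RANGES = {
    "miRNA": (20, 24),
    "YRNA": (25, 35),
    "tRNA": (28, 36),
    "piRNA": (26, 32),
    "protein_coding": (18, 40),
    "other": (18, 40),
}


@dataclass(frozen=True)
class PlantedEffect:
    """A log2 fold change planted on a set of reference rows.

    ``group`` may be a clinical group (``control``/``MCI``/``AD``), a
    converter group (applied in full to that converter group only — a
    converter-unique signature), or a postmortem pathology label (applied to
    samples whose latent pathology matches, e.g. ``PART``).
    """

    rows: tuple[int, ...]
    group: str
    log2fc: float

    def __init__(self, rows: Sequence[int], group: str, log2fc: float):
        object.__setattr__(self, "rows", tuple(rows))
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "log2fc", float(log2fc))
        valid = set(STATIC_GROUPS) | set(CONVERTER_GROUPS) | set(PATHOLOGIES)
        if group not in valid:
            raise ValueError(f"unknown effect group {group!r}")


@dataclass(frozen=True)
class TrendGene:
    """Linear log2 trend in time-to-conversion for converter samples.

    ``slope`` is in log2 normalized-expression units per year on the axis
    x = -years_to_conversion (so a positive slope means expression rises as
    the conversion date approaches).
    """

    row: int
    slope: float


@dataclass
class SimulationDesign:
    """All knobs of the synthetic cohort, with study-scale defaults."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "control": 40,
            "MCI": 18,
            "AD": 32,
            "C_to_MCI": 9,
            "C_to_AD": 6,
            "MCI_to_AD": 6,
        }
    )
    n_genes_per_biotype: dict[str, int] = field(
        default_factory=lambda: {
            "miRNA": 250,
            "YRNA": 60,
            "tRNA": 80,
            "piRNA": 50,
            "protein_coding": 50,
            "other": 30,
        }
    )
    #: family size per canonical gene = 1 + Poisson(mean - 1)
    isomir_mean_family_size: float = 2.0
    library_size_mean: float = 2_000_000.0
    #: log-sd of the per-sample library-size factor
    library_size_sigma: float = 0.4
    #: log-sd of baseline per-sequence abundance (heavy skew: a few dominant
    #: transcripts carry most reads, as plasma small-RNA profiles do)
    abundance_sigma: float = 1.8
    #: per-gene NB dispersion phi, Var = mu + phi mu^2 (scalar or per-row array)
    gene_dispersion: float = 0.2
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    #: fraction of the full disease effect expressed in converter samples
    converter_effect_scale: float = 0.5
    trend_genes: list[TrendGene] = field(default_factory=list)
    #: multiplicative inflation of per-gene %CV in the EV-depleted fraction
    depleted_fraction_cv_inflation: float = 2.0
    #: fraction of genes absent from the depleted fraction altogether
    depleted_dropout_rate: float = 0.3
    #: EV-depleted counterparts generated for the first k samples per group
    n_depleted_per_group: dict[str, int] = field(
        default_factory=lambda: {"control": 16, "MCI": 10, "AD": 16}
    )
    #: probability a sample has autopsy (postmortem) data at all
    autopsy_rate: float = 0.4
    #: conditional pathology rates among autopsied samples
    pathology_mislabel_rates: dict[str, float] = field(
        default_factory=lambda: {
            "control_PART": 0.30,
            "control_AD": 0.25,
            "MCI_DLB": 0.15,
            "MCI_other": 0.10,
            "AD_other": 0.10,
        }
    )
    years_to_conversion_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "C_to_AD": (2.0, 12.0),
            "C_to_MCI": (2.0, 9.0),
            "MCI_to_AD": (1.0, 2.0),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group is empty")
        for g, n in self.n_per_group.items():
            if g not in STATIC_GROUPS + CONVERTER_GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size")
        if any(n <= 0 for n in self.n_genes_per_biotype.values()):
            raise ValueError("n_genes_per_biotype must be positive")
        if not 0.0 <= self.converter_effect_scale <= 1.0:
            raise ValueError("converter_effect_scale must be in [0, 1]")
        if not 0.0 <= self.depleted_dropout_rate <= 1.0:
            raise ValueError("depleted_dropout_rate must be in [0, 1]")
        if self.depleted_fraction_cv_inflation < 1.0:
            raise ValueError("depleted_fraction_cv_inflation must be >= 1")


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent child stream per artifact."""
    ref_ss, meta_ss, counts_ss, reads_ss = np.random.SeedSequence(seed).spawn(4)
    return {
        "reference": np.random.default_rng(ref_ss),
        "metadata": np.random.default_rng(meta_ss),
        "counts": np.random.default_rng(counts_ss),
        "reads": np.random.default_rng(reads_ss),
    }


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str) -> str:
    """Derive an isomiR: substitution, end-trim, or 3' extension."""
    op = rng.integers(0, 4)
    s = list(seq)
    if op == 0 and len(s) > 16:  # 5' trim
        return "".join(s[int(rng.integers(1, 3)) :])
    if op == 1 and len(s) > 16:  # 3' trim
        return "".join(s[: len(s) - int(rng.integers(1, 3))])
    if op == 2 and len(s) < 44:  # 3' extension (non-templated addition)
        return seq + _random_seq(rng, int(rng.integers(1, 3)))
    pos = int(rng.integers(0, len(s)))
    s[pos] = str(rng.choice([c for c in "ACGT" if c != s[pos]]))
    return "".join(s)


def simulate_reference(design: SimulationDesign) -> AnnotatedReference:
    """Generate an annotated reference with isomiR families, deterministically."""
    design.validate()
    rng = _rng_streams(design.seed)["reference"]
    seen: set[str] = set()
    entries: list[ReferenceEntry] = []
    for biotype in BIOTYPES:
        n_genes = design.n_genes_per_biotype.get(biotype, 0)
        lo, hi = LENGTH_RANGES[biotype]
        for gi in range(n_genes):
            gene = f"{GENE_PREFIX[biotype]}-{gi + 1}"
            if design.isomir_mean_family_size <= 1.0:
                fam = 1
            else:
                fam = 1 + int(rng.poisson(design.isomir_mean_family_size - 1.0))
            base = None
            for _ in range(200):
                cand = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                if cand not in seen:
                    base = cand
                    break
            if base is None:
                raise RuntimeError("could not draw a unique sequence after 200 tries")
            seen.add(base)
            entries.append(ReferenceEntry(base, gene, biotype))
            for _ in range(fam - 1):
                var = None
                for _ in range(200):
                    cand = _mutate(rng, base)
                    if cand not in seen and 15 <= len(cand) <= 45:
                        var = cand
                        break
                if var is None:
                    raise RuntimeError(
                        f"could not derive a unique isomiR for {gene} after 200 tries"
                    )
                seen.add(var)
                entries.append(ReferenceEntry(var, gene, biotype))
    return AnnotatedReference(entries)


# ---------------------------------------------------------------------------
# metadata

_DRS = {"control": (140.0, 3.0), "MCI": (128.0, 5.0), "AD": (115.0, 9.0)}
_MMSE = {"control": (29.0, 1.0), "MCI": (26.0, 1.5), "AD": (19.0, 4.0)}
_APOE = ["E2/E2", "E2/E3", "E2/E4", "E3/E3", "E3/E4", "E4/E4"]
_APOE_P = {
    "control": [0.01, 0.13, 0.02, 0.62, 0.19, 0.03],
    "MCI": [0.005, 0.10, 0.02, 0.555, 0.27, 0.05],
    "AD": [0.0, 0.05, 0.02, 0.45, 0.36, 0.12],
    "converter": [0.0, 0.06, 0.02, 0.47, 0.36, 0.09],
}

_DX_AT_DRAW = {
    "control": "control",
    "MCI": "MCI",
    "AD": "AD",
    "C_to_MCI": "control",
    "C_to_AD": "control",
    "MCI_to_AD": "MCI",
}
_CONVERTS_TO = {"C_to_MCI": "MCI", "C_to_AD": "AD", "MCI_to_AD": "AD"}


def _draw_pathology(rng: np.random.Generator, group: str,
                    rates: Mapping[str, float]) -> str:
    """Latent (true) pathology for one sample; observed only at autopsy."""
    u = rng.random()
    if group == "control":
        if u < rates.get("control_PART", 0.0):
            return "PART"
        if u < rates.get("control_PART", 0.0) + rates.get("control_AD", 0.0):
            return "AD"
        return "normal"
    if group == "MCI":
        if u < rates.get("MCI_DLB", 0.0):
            return "DLB"
        if u < rates.get("MCI_DLB", 0.0) + rates.get("MCI_other", 0.0):
            return "FTD" if rng.random() < 0.5 else "vascular"
        return "AD"
    if group == "AD":
        if u < rates.get("AD_other", 0.0):
            return "DLB" if rng.random() < 0.5 else "vascular"
        return "AD"
    # converters: pathology reflects the destination diagnosis
    if group in ("C_to_AD", "MCI_to_AD"):
        return "AD"
    return "AD" if rng.random() < 0.4 else "normal"


def _simulate_metadata(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in design.n_per_group.items():
        dx = _DX_AT_DRAW[group]
        for i in range(n):
            years = 0.0
            if group in CONVERTER_GROUPS:
                lo, hi = design.years_to_conversion_range[group]
                years = round(float(rng.uniform(lo, hi)), 1)
            latent = _draw_pathology(rng, group, design.pathology_mislabel_rates)
            autopsied = rng.random() < design.autopsy_rate
            drs_m, drs_s = _DRS[dx]
            mmse_m, mmse_s = _MMSE[dx]
            apoe_p = _APOE_P["converter" if group in CONVERTER_GROUPS else dx]
            rows.append(
                {
                    "sample_id": f"{group}-{i + 1:02d}-EV",
                    "group": group,
                    "fraction": "EV",
                    "dx_at_draw": dx,
                    # observed pathology: latent truth revealed only at autopsy
                    "postmortem_dx": latent if autopsied else "unknown",
                    "latent_pathology": latent,
                    "converts_to": _CONVERTS_TO.get(group, "none"),
                    "years_to_conversion": years,
                    "DRS": int(np.clip(round(rng.normal(drs_m, drs_s)), 0, 144)),
                    "MMSE": int(np.clip(round(rng.normal(mmse_m, mmse_s)), 0, 30)),
                    "apoe": str(rng.choice(_APOE, p=apoe_p)),
                    "sex": str(rng.choice(["M", "F"])),
                    "age": round(float(np.clip(rng.normal(74.0, 6.0), 55.0, 95.0)), 1),
                }
            )
    # EV-depleted counterparts share the donor's clinical metadata
    dep_rows = []
    for group, k in design.n_depleted_per_group.items():
        donors = [r for r in rows if r["group"] == group][:k]
        for r in donors:
            d = dict(r)
            d["sample_id"] = r["sample_id"].replace("-EV", "-DEP")
            d["fraction"] = "depleted"
            dep_rows.append(d)
    df = pd.DataFrame(rows + dep_rows)
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# counts

def _effect_weight(group: str, pathology: str, eff: PlantedEffect, scale: float) -> float:
    """Log2-effect weight of a planted effect for one sample.

    Converters express ``scale`` of the destination group's effect on top of
    ``1 - scale`` (for MCI->AD) or none (for control->*) of the origin's.
    """
    g = eff.group
    if g in CONVERTER_GROUPS:
        return 1.0 if group == g else 0.0
    if g not in STATIC_GROUPS and g in PATHOLOGIES:
        # pathology-keyed effect (e.g. PART): clinical names take precedence
        return 1.0 if pathology == g else 0.0
    if group == g:
        return 1.0
    if group == "C_to_MCI" and g == "MCI":
        return scale
    if group == "C_to_AD" and g == "AD":
        return scale
    if group == "MCI_to_AD":
        if g == "AD":
            return scale
        if g == "MCI":
            return 1.0 - scale
    return 0.0


def simulate_cohort(
    design: SimulationDesign, reference: AnnotatedReference
) -> tuple[pd.DataFrame, SequenceCountMatrix]:
    """Draw sample metadata and a sequence-level NB count matrix."""
    design.validate()
    streams = _rng_streams(design.seed)
    metadata = _simulate_metadata(design, streams["metadata"])

    rng = streams["counts"]
    n_seq = len(reference)
    n_samples = len(metadata)

    abundance = rng.lognormal(mean=0.0, sigma=design.abundance_sigma, size=n_seq)
    rel = abundance / abundance.sum()
    lib = design.library_size_mean * rng.lognormal(
        mean=-design.library_size_sigma**2 / 2.0,
        sigma=design.library_size_sigma,
        size=n_samples,
    )
    dropout = rng.random(n_seq) < design.depleted_dropout_rate

    phi = np.broadcast_to(np.asarray(design.gene_dispersion, dtype=float), (n_seq,)).copy()

    # planted log2 offsets, per gene x sample
    delta = np.zeros((n_seq, n_samples))
    groups = metadata["group"].to_numpy()
    pathologies = metadata["latent_pathology"].to_numpy()
    years = metadata["years_to_conversion"].to_numpy(dtype=float)
    is_converter = np.isin(groups, CONVERTER_GROUPS)
    for eff in design.planted_effects:
        w = np.array(
            [
                _effect_weight(g, pm, eff, design.converter_effect_scale)
                for g, pm in zip(groups, pathologies)
            ]
        )
        delta[np.asarray(eff.rows)[:, None], :] += eff.log2fc * w[None, :]
    for tg in design.trend_genes:
        delta[tg.row, is_converter] += tg.slope * (-years[is_converter])

    mu = rel[:, None] * lib[None, :] * np.exp2(delta)

    # EV-depleted fraction: gene dropout + extra multiplicative noise chosen so
    # the per-gene %CV is multiplied by roughly the design inflation factor.
    dep_mask = (metadata["fraction"] == "depleted").to_numpy()
    if dep_mask.any():
        mu[np.ix_(dropout, dep_mask)] = 0.0
        c = design.depleted_fraction_cv_inflation
        if c > 1.0:
            mean_count = rel * design.library_size_mean
            c0sq = 1.0 / np.maximum(mean_count, 1e-9) + phi
            v = c0sq * (c**2 - 1.0) / (1.0 + phi)
            sigma = np.sqrt(np.log1p(v))
            noise = rng.normal(size=(n_seq, int(dep_mask.sum())))
            mult = np.exp(sigma[:, None] * noise - sigma[:, None] ** 2 / 2.0)
            mu[:, dep_mask] *= mult

    # gamma-Poisson mixture: Var = mu + phi mu^2
    counts = np.zeros_like(mu, dtype=np.int64)
    pos_phi = phi > 0
    if pos_phi.any():
        shape = 1.0 / phi[pos_phi]
        lam = rng.gamma(shape[:, None], mu[pos_phi, :] * phi[pos_phi, None])
        counts[pos_phi, :] = rng.poisson(lam)
    if (~pos_phi).any():
        counts[~pos_phi, :] = rng.poisson(mu[~pos_phi, :])

    seqs = [e.sequence for e in reference]
    table = pd.DataFrame(counts, index=pd.Index(seqs, name="sequence"),
                         columns=metadata.index)
    table = table.loc[table.sum(axis=1) > 0]
    matrix = build_count_matrix(table, reference)
    return metadata, matrix


def choose_expressed_rows(
    design: SimulationDesign,
    reference: AnnotatedReference,
    min_count: float = 10,
    min_frac: float = 0.5,
) -> list[int]:
    """Reference row indices whose sequences would pass the expression filter
    under the (effect-free) design.

    Useful for planting effects on genes the downstream analysis will
    actually test: the baseline abundance draw depends only on the seed, so
    the same rows stay expressed once effects are added.
    """
    probe = SimulationDesign(**{**vars(design), "planted_effects": [],
                                "trend_genes": []})
    _, matrix = simulate_cohort(probe, reference)
    frac = (matrix.counts > min_count).sum(axis=1) / matrix.counts.shape[1]
    kept_seqs = set(matrix.sequences[frac >= min_frac])
    return [i for i, e in enumerate(reference) if e.sequence in kept_seqs]


# ---------------------------------------------------------------------------
# reads

def simulate_reads(
    matrix: SequenceCountMatrix,
    reference: AnnotatedReference,
    out_dir: str | Path,
    adapter: str = DEFAULT_ADAPTER,
    n_random: int = 4,
    seed: int = 0,
    quality_char: str = "I",
) -> list[Path]:
    """Emit per-sample FASTQ files realizing the count matrix.

    Each count unit becomes one read: 4 random nt + insert + 4 random nt +
    adapter, with a constant quality string. The per-sample read count equals
    the column sum, so read processing round-trips to the input matrix.
    """
    if set(adapter) - set("ACGT"):
        raise ValueError("adapter must be over {A,C,G,T}")
    for s in matrix.sequences:
        if s not in reference.by_sequence:
            raise KeyError(f"sequence {s!r} not in reference")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    for sample in matrix.sample_ids:
        col = matrix.counts[sample]
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            i = 0
            for seq, c in zip(matrix.sequences, col):
                if c == 0:
                    continue
                flanks = _NT[rng.integers(0, 4, size=(c, 2 * n_random))]
                lines = []
                for r in range(c):
                    f = "".join(flanks[r])
                    read = f[:n_random] + seq + f[n_random:] + adapter
                    i += 1
                    lines.append(
                        f"@{sample}:{i}\n{read}\n+\n{quality_char * len(read)}\n"
                    )
                fh.writelines(lines)
        paths.append(path)
    return paths


def write_design(design: SimulationDesign, path: str | Path) -> None:
    """Serialize a design to YAML (nested key-value sections)."""
    import yaml

    d = {
        "n_per_group": dict(design.n_per_group),
        "n_genes_per_biotype": dict(design.n_genes_per_biotype),
        "isomir_mean_family_size": design.isomir_mean_family_size,
        "library_size_mean": design.library_size_mean,
        "library_size_sigma": design.library_size_sigma,
        "abundance_sigma": design.abundance_sigma,
        "gene_dispersion": float(np.mean(design.gene_dispersion)),
        "planted_effects": [
            {"rows": list(e.rows), "group": e.group, "log2fc": e.log2fc}
            for e in design.planted_effects
        ],
        "converter_effect_scale": design.converter_effect_scale,
        "trend_genes": [{"row": t.row, "slope": t.slope} for t in design.trend_genes],
        "depleted_fraction_cv_inflation": design.depleted_fraction_cv_inflation,
        "depleted_dropout_rate": design.depleted_dropout_rate,
        "n_depleted_per_group": dict(design.n_depleted_per_group),
        "autopsy_rate": design.autopsy_rate,
        "pathology_mislabel_rates": dict(design.pathology_mislabel_rates),
        "years_to_conversion_range": {
            k: list(v) for k, v in design.years_to_conversion_range.items()
        },
        "seed": design.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_design(path: str | Path) -> SimulationDesign:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["planted_effects"] = [
        PlantedEffect(e["rows"], e["group"], e["log2fc"])
        for e in d.get("planted_effects", [])
    ]
    d["trend_genes"] = [TrendGene(t["row"], t["slope"]) for t in d.get("trend_genes", [])]
    d["years_to_conversion_range"] = {
        k: tuple(v) for k, v in d.get("years_to_conversion_range", {}).items()
    }
    return SimulationDesign(**d)
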