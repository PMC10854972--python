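"""End-to-end orchestration: simulate -> count -> curate -> DE -> classify ->
project -> trend, from a single config, with a machine-readable run report.

Each stage writes its outputs before the next stage reads them, and every
stage draws its randomness from a child of the master seed, so a run is fully
reproducible and stages can be re-executed in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import AnnotatedReference, SequenceCountMatrix, validate_metadata
from .curation import (
    apoe_crosstab,
    apply_curation_rules,
    build_part_model,
    flag_suspected_part,
    summarize_curation,
)
from .elnet import project_new_samples, three_loop_elastic_net
from .reads import DEFAULT_ADAPTER, biotype_composition, count_fastq_dir, qc_filter_samples
from .regression import fit_evaluate_lrm, select_top10, time_to_conversion_regression
from .simulate import SimulationDesign, simulate_cohort, simulate_reads, simulate_reference
from .stats import (
    detection_overlap,
    nb_wald_de,
    normalize,
    percent_cv_comparison,
    size_factors,
)

log = logging.getLogger("evrna")

#: converter group -> (model comparison used to project it)
CONVERTER_MODEL = {
    "C_to_AD": ("control", "AD"),
    "C_to_MCI": ("control", "MCI"),
    "MCI_to_AD": ("MCI", "AD"),
}


@dataclass
class RunConfig:
    outdir: str = "evrna_run"
    #: optional pre-made inputs; when absent, the synthetic cohort is used
    counts_tsv: str | None = None
    lookup_tsv: str | None = None
    metadata_tsv: str | None = None
    fastq_dir: str | None = None
    reference_tsv: str | None = None
    #: simulate reads and push them through read processing (slow but exact
    #: end-to-end); otherwise the simulated count matrix is used directly
    simulate_fastq: bool = False
    design: SimulationDesign = field(default_factory=SimulationDesign)

    adapter: str = DEFAULT_ADAPTER
    n_random: int = 4
    min_len: int = 15
    min_mapped: int = 1_000_000
    min_count: float = 10
    min_frac: float = 0.5
    de_alpha: float = 0.05
    elnet_alpha: float = 0.5
    n_iter: int = 1000
    lrm_repeats: int = 100
    lrm_criterion: str = "padj"
    r2_min: float = 0.66
    part_cutoff: float = 0.5
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("control", "AD"), ("control", "MCI"), ("MCI", "AD")]
    )
    seed: int = 0

    def validate(self) -> None:
        for name, v, lo, hi in [
            ("min_frac", self.min_frac, 0, 1),
            ("de_alpha", self.de_alpha, 0, 1),
            ("elnet_alpha", self.elnet_alpha, 0, 1),
            ("part_cutoff", self.part_cutoff, 0, 1),
            ("r2_min", self.r2_min, 0, 1),
        ]:
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_iter < 1 or self.lrm_repeats < 1:
            raise ValueError("iteration counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        from .simulate import PlantedEffect, TrendGene

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "comparisons" in d:
            d["comparisons"] = [tuple(c) for c in d["comparisons"]]
        if "design" in d:
            dd = d["design"]
            dd["planted_effects"] = [
                PlantedEffect(e["rows"], e["group"], e["log2fc"])
                for e in dd.get("planted_effects", [])
            ]
            dd["trend_genes"] = [
                TrendGene(t["row"], t["slope"]) for t in dd.get("trend_genes", [])
            ]
            if "years_to_conversion_range" in dd:
                dd["years_to_conversion_range"] = {
                    k: tuple(v) for k, v in dd["years_to_conversion_range"].items()
                }
            d["design"] = SimulationDesign(**dd)
        return cls(**d)


def de_summary(de_tables: dict[str, pd.DataFrame], lookup: pd.DataFrame,
               alpha: float = 0.05) -> dict:
    """Per-comparison DE summary: n significant (unadjusted p < alpha), biotype
    percentages of the significant set, and the miRNA vs non-miRNA split."""
    out = {}
    for name, table in de_tables.items():
        sig = table[table["p"].notna() & (table["p"] < alpha)]
        n = len(sig)
        entry: dict = {"n_significant": n, "empty": n == 0}
        if n:
            bt = lookup.loc[sig.index, "biotype"].value_counts()
            entry["pct_by_biotype"] = {b: round(100.0 * c / n, 2) for b, c in bt.items()}
            mi = int(bt.get("miRNA", 0))
            entry["pct_miRNA"] = round(100.0 * mi / n, 2)
            entry["pct_non_miRNA"] = round(100.0 * (n - mi) / n, 2)
        else:
            entry["pct_by_biotype"] = {}
            entry["pct_miRNA"] = 0.0
            entry["pct_non_miRNA"] = 0.0
        out[name] = entry
    return out


def _stage_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence(master).spawn(k + 1)[k].generate_state(1)[0]
               % (2**31))


def run_all(config: RunConfig) -> dict:
    """Execute every stage in dependency order; returns the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"][name] = {"status": "running"}
        return report["stages"][name]

    try:
        # ------------------------------------------------------ inputs
        st = stage("inputs")
        if config.counts_tsv:
            matrix = SequenceCountMatrix.from_tsv(config.counts_tsv, config.lookup_tsv)
            metadata = validate_metadata(pd.read_csv(config.metadata_tsv, sep="\t"))
            st["source"] = "provided_counts"
            st["read_processing"] = "skipped (counts provided)"
        else:
            design = config.design
            design.seed = config.seed
            reference = (
                AnnotatedReference.from_tsv(config.reference_tsv)
                if config.reference_tsv
                else simulate_reference(design)
            )
            metadata, matrix = simulate_cohort(design, reference)
            if config.simulate_fastq:
                fq_dir = outdir / "fastq"
                simulate_reads(matrix, reference, fq_dir, adapter=config.adapter,
                               n_random=config.n_random,
                               seed=_stage_seed(config.seed, 0))
                matrix, qc_report = count_fastq_dir(
                    fq_dir, reference, adapter=config.adapter,
                    n_random=config.n_random, min_len=config.min_len,
                    min_mapped=config.min_mapped,
                )
                st["qc"] = {"excluded": qc_report["qc_excluded_samples"]}
            st["source"] = "synthetic"
            reference.to_tsv(outdir / "reference.tsv")
        metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        matrix.to_tsv(outdir / "counts.tsv", outdir / "lookup.tsv")
        st["n_sequences"], st["n_samples"] = matrix.counts.shape
        st["status"] = "complete"

        # ------------------------------------------------------ sample QC
        st = stage("sample_qc")
        matrix, excluded = qc_filter_samples(matrix, config.min_mapped)
        metadata = metadata.loc[[s for s in metadata.index if s in matrix.sample_ids]]
        st["excluded_samples"] = excluded
        st["n_samples_kept"] = len(matrix.sample_ids)
        st["status"] = "complete"

        ev_samples = metadata.index[metadata["fraction"] == "EV"]
        dep_samples = metadata.index[metadata["fraction"] == "depleted"]
        ev = matrix.subset_samples(ev_samples)

        # ------------------------------------------------ fraction comparison
        st = stage("fraction_comparison")
        if len(dep_samples) >= 2:
            dep = matrix.subset_samples(dep_samples)
            cv = percent_cv_comparison(
                normalize(ev.counts), normalize(dep.counts),
                min_count=config.min_count, min_frac=config.min_frac,
            )
            ov = detection_overlap(ev, dep)
            comp, div = biotype_composition(matrix)
            comp.to_csv(outdir / "biotype_composition.tsv", sep="\t")
            div.to_csv(outdir / "biotype_diversity.tsv", sep="\t")
            pd.DataFrame({"EV": cv.cv_a, "depleted": cv.cv_b}).to_csv(
                outdir / "percent_cv.tsv", sep="\t")
            st.update(
                {
                    "median_cv_EV": float(cv.cv_a.median()),
                    "median_cv_depleted": float(cv.cv_b.median()),
                    "welch_p": cv.p,
                    "detected_both": ov.n_both,
                    "detected_EV_only": ov.n_a_only,
                    "detected_depleted_only": ov.n_b_only,
                }
            )
            st["status"] = "complete"
        else:
            st["status"] = "skipped (no depleted fraction)"

        # ------------------------------------------------------ curation
        st = stage("curation")
        md_ev = metadata.loc[ev_samples]
        flagged: list[str] = []
        part_info = None
        n_part = int(((md_ev["dx_at_draw"] == "control")
                      & (md_ev["postmortem_dx"] == "PART")
                      & (md_ev["converts_to"] == "none")).sum())
        n_norm = int(((md_ev["dx_at_draw"] == "control")
                      & (md_ev["postmortem_dx"] == "normal")
                      & (md_ev["converts_to"] == "none")).sum())
        if n_part >= 2 and n_norm >= 2:
            part_model, part_perf = build_part_model(
                ev.counts, md_ev, alpha=config.elnet_alpha, n_iter=config.n_iter,
                seed=_stage_seed(config.seed, 1), min_count=config.min_count,
                min_frac=config.min_frac,
            )
            flagged = flag_suspected_part(part_model, ev.counts, md_ev,
                                          cutoff=config.part_cutoff)
            part_info = {
                "n_features": len(part_model.features),
                "features": part_model.features,
                "best_training_accuracy": part_perf.best_accuracy,
                "mean_holdout_accuracy": part_perf.mean_accuracy,
            }
        curated = apply_curation_rules(md_ev, flagged)
        curated.to_csv(outdir / "curated_metadata.tsv", sep="\t", index=False)
        cur_report = summarize_curation(curated, flagged)
        st["part_model"] = part_info
        st.update(cur_report.to_dict())
        st["status"] = "complete"

        apoe = apoe_crosstab(md_ev, curated["final_group"])
        apoe.to_csv(outdir / "apoe_crosstab.tsv", sep="\t")

        labels = curated["final_group"]

        # ------------------------------------------------- DE + classification
        de_tables: dict[str, pd.DataFrame] = {}
        de_results = {}
        st = stage("differential_expression")
        for g1, g2 in config.comparisons:
            s1 = list(labels.index[labels == g1])
            s2 = list(labels.index[labels == g2])
            name = f"{g1}_vs_{g2}"
            if len(s1) < 2 or len(s2) < 2:
                st[name] = "skipped (insufficient samples)"
                continue
            de = nb_wald_de(ev.counts, s1, s2, min_count=config.min_count,
                            min_frac=config.min_frac, comparison=name)
            de.group1, de.group2 = g1, g2
            de_results[name] = de
            table = de.table.join(ev.annotation[["sequence", "biotype"]])
            table.to_csv(outdir / f"de_{name}.tsv", sep="\t")
            de_tables[name] = de.table
            st[name] = {
                "n_tested": int(de.table["p"].notna().sum()),
                "n_significant_p": int(len(de.significant(config.de_alpha))),
                "n_significant_padj": int(
                    len(de.significant(config.de_alpha, adjusted=True))),
            }
        st["summary"] = de_summary(de_tables, ev.annotation, config.de_alpha)
        st["status"] = "complete"

        st = stage("classification")
        models = {}
        for i, (g1, g2) in enumerate(config.comparisons):
            name = f"{g1}_vs_{g2}"
            if name not in de_results:
                continue
            try:
                model, perf = three_loop_elastic_net(
                    ev.counts, labels, g1, g2, de=de_results[name],
                    alpha=config.elnet_alpha, alpha_p=config.de_alpha,
                    n_iter=config.n_iter, seed=_stage_seed(config.seed, 2 + i),
                )
            except ValueError as err:
                st[name] = f"skipped ({err})"
                continue
            models[(g1, g2)] = model
            perf.probabilities.rename("probability").to_csv(
                outdir / f"waterfall_{name}.tsv", sep="\t")
            with open(outdir / f"elnet_{name}.json", "w") as fh:
                json.dump(
                    {
                        "alpha": model.alpha,
                        "lambda": model.lam,
                        "features": model.features,
                        "coefficients": model.coef.tolist(),
                        "intercept": model.intercept,
                        "classes": list(model.classes),
                    },
                    fh, indent=2,
                )
            entry = {
                "n_features": len(model.features),
                "lambda": model.lam,
                "mean_accuracy": perf.mean_accuracy,
                "sd_accuracy": perf.sd_accuracy,
                "mean_auc": perf.mean_auc,
                "sd_auc": perf.sd_auc,
            }
            # benchmark: unpenalized logistic model on the top-10 DE genes
            top10 = select_top10(de_results[name], by=config.lrm_criterion)
            s1 = list(labels.index[labels == g1])
            s2 = list(labels.index[labels == g2])
            sub = ev.counts[s1 + s2]
            x = normalize(sub).loc[top10].T
            y = np.array([0] * len(s1) + [1] * len(s2))
            lrm = fit_evaluate_lrm(x, y, n_repeats=config.lrm_repeats,
                                   seed=_stage_seed(config.seed, 10 + i),
                                   criterion=config.lrm_criterion)
            entry["lrm"] = {
                "genes": lrm.genes,
                "mean_accuracy": lrm.mean_accuracy,
                "sd_accuracy": lrm.sd_accuracy,
                "mean_auc": lrm.mean_auc,
                "sd_auc": lrm.sd_auc,
            }
            st[name] = entry
        st["status"] = "complete"

        # -------------------------------------------- converter projection
        st = stage("converter_projection")
        for conv_group, (g1, g2) in CONVERTER_MODEL.items():
            conv_samples = list(labels.index[labels == conv_group])
            if not conv_samples or (g1, g2) not in models:
                st[conv_group] = "skipped"
                continue
            proj = project_new_samples(models[(g1, g2)], ev.counts[conv_samples])
            proj.to_csv(outdir / f"projection_{conv_group}.tsv", sep="\t")
            st[conv_group] = {
                "model": f"{g1}_vs_{g2}",
                "n_projected": len(proj),
                "n_assigned_disease": int((proj["assigned_class"] == g2).sum()),
                "mean_probability": float(proj["probability"].mean()),
            }
        st["status"] = "complete"

        # ------------------------------------------------- trend regression
        st = stage("trend_regression")
        sf = size_factors(ev.counts)
        logq = np.log2(ev.counts / sf + 1.0)
        for conv_group in ("C_to_AD", "C_to_MCI", "MCI_to_AD"):
            conv_samples = list(labels.index[labels == conv_group])
            if len(conv_samples) < 3:
                st[conv_group] = "skipped (<3 converters)"
                continue
            years = metadata.loc[conv_samples, "years_to_conversion"]
            trends = time_to_conversion_regression(
                logq[conv_samples], years, r2_min=config.r2_min,
                alpha=config.de_alpha,
            )
            trends.to_csv(outdir / f"trend_{conv_group}.tsv", sep="\t")
            st[conv_group] = {
                "n_tested": len(trends),
                "n_flagged": int(trends["flagged"].sum()),
            }
        st["status"] = "complete"

    except Exception as err:
        failed = [k for k, v in report["stages"].items()
                  if v.get("status") == "running"]
        raise RuntimeError(
            f"pipeline failed in stage {failed[-1] if failed else '?'}: {err}"
        ) from err

    report["config"] = {
        k: v for k, v in vars(config).items() if not isinstance(v, SimulationDesign)
    }
    report["config"]["comparisons"] = [list(c) for c in config.comparisons]
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
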