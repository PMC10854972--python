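"""Pathology-informed cohort curation.

Clinical diagnosis at blood draw does not always match postmortem pathology:
controls may carry PART or even AD pathology, and MCI patients may turn out
to have Lewy-body disease. Curation reconciles diagnosis, pathology and
conversion status into the final analysis groups:

1. controls (who never converted) with postmortem AD pathology -> excluded;
2. controls with autopsy-confirmed PART -> excluded from disease comparisons
   (they still train the PART model);
3. controls without autopsy whom the PART model flags at >= the probability
   cutoff -> excluded;
4. MCI (who never converted) with postmortem DLB -> excluded;
5. optionally, non-converters whose pathology is FTD or vascular -> excluded;
6. participants whose diagnosis progressed after the draw -> converter groups
   (C_to_MCI / C_to_AD / MCI_to_AD);
7. everyone else keeps the diagnosis at draw.

Pathology exclusions are evaluated before converter assignment but apply only
to non-converters: a converter whose autopsy later confirmed the destination
diagnosis is evidence the conversion was real, not grounds for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import validate_metadata
from .elnet import ElasticNetModel, ModelPerformance, three_loop_elastic_net

EXCLUSION_REASONS = (
    "pathology_AD_in_control",
    "DLB_in_MCI",
    "predicted_PART",
    "confirmed_PART",
    "other",
    "none",
)


def build_part_model(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.5,
    n_iter: int = 1000,
    seed: int = 0,
    min_count: float = 10,
    min_frac: float = 0.5,
    alpha_p: float = 0.05,
) -> tuple[ElasticNetModel, ModelPerformance]:
    """Elastic-net model separating autopsy-confirmed normal vs PART controls.

    Uses the full three-loop procedure on control samples (EV fraction) whose
    postmortem diagnosis is ``normal`` or ``PART``.
    """
    md = validate_metadata(metadata)
    ctl = md[(md["dx_at_draw"] == "control") & (md["converts_to"] == "none")
             & (md["fraction"] == "EV")]
    part = ctl[ctl["postmortem_dx"] == "PART"]
    norm = ctl[ctl["postmortem_dx"] == "normal"]
    if len(part) < 2 or len(norm) < 2:
        raise ValueError(
            f"need >= 2 controls per pathology class (normal: {len(norm)}, "
            f"PART: {len(part)})"
        )
    labels = pd.Series("normal", index=norm.index).reindex(
        list(norm.index) + list(part.index), fill_value="PART"
    )
    sub = counts[list(labels.index)]
    return three_loop_elastic_net(
        sub, labels, "normal", "PART", alpha=alpha, alpha_p=alpha_p,
        n_iter=n_iter, seed=seed, min_count=min_count, min_frac=min_frac,
    )


def flag_suspected_part(
    model: ElasticNetModel,
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    cutoff: float = 0.5,
) -> list[str]:
    """Controls without autopsy data whose PART-class probability is
    >= ``cutoff`` (inclusive: 50%-or-greater confidence flags the sample)."""
    md = validate_metadata(metadata)
    unknown = md[(md["dx_at_draw"] == "control") & (md["converts_to"] == "none")
                 & (md["postmortem_dx"] == "unknown") & (md["fraction"] == "EV")]
    if len(unknown) == 0:
        return []
    prob = model.predict_proba_counts(counts[list(unknown.index)])
    return sorted(prob.index[prob >= cutoff])


def apply_curation_rules(
    metadata: pd.DataFrame,
    flagged_part: list[str] | None = None,
    exclude_other_pathologies: bool = True,
) -> pd.DataFrame:
    """Assign every sample a final group and an exclusion reason.

    Returns the metadata with ``final_group`` (control / MCI / AD / C_to_MCI /
    C_to_AD / MCI_to_AD / excluded) and ``exclusion_reason`` columns.
    """
    md = validate_metadata(metadata)
    flagged = set(flagged_part or [])
    groups, reasons = [], []
    for sid, row in md.iterrows():
        dx, pm, conv = row["dx_at_draw"], row["postmortem_dx"], row["converts_to"]
        if dx == "AD" and conv != "none":
            raise ValueError(f"sample {sid}: AD at draw cannot be a converter")
        if conv not in ("none", "MCI", "AD"):
            raise ValueError(f"sample {sid}: invalid conversion target {conv!r}")
        if dx == "MCI" and conv == "MCI":
            raise ValueError(f"sample {sid}: MCI 'converting' to MCI")
        group, reason = None, "none"
        if conv == "none":
            if dx == "control" and pm == "AD":
                group, reason = "excluded", "pathology_AD_in_control"
            elif dx == "control" and pm == "PART":
                group, reason = "excluded", "confirmed_PART"
            elif dx == "control" and sid in flagged:
                group, reason = "excluded", "predicted_PART"
            elif dx == "MCI" and pm == "DLB":
                group, reason = "excluded", "DLB_in_MCI"
            elif exclude_other_pathologies and pm in ("FTD", "vascular"):
                group, reason = "excluded", "other"
            else:
                group = dx
        else:
            if dx == "control":
                group = "C_to_MCI" if conv == "MCI" else "C_to_AD"
            else:  # MCI -> AD
                group = "MCI_to_AD"
        groups.append(group)
        reasons.append(reason)
    out = md.copy()
    out["final_group"] = groups
    out["exclusion_reason"] = reasons
    return out


@dataclass
class CurationReport:
    n_samples: int
    group_sizes: dict[str, int]
    exclusions_by_reason: dict[str, int]
    flagged_suspected_part: list[str]

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "group_sizes": self.group_sizes,
            "exclusions_by_reason": self.exclusions_by_reason,
            "flagged_suspected_part": self.flagged_suspected_part,
        }


def summarize_curation(curated: pd.DataFrame,
                       flagged: list[str] | None = None) -> CurationReport:
    reasons = curated.loc[curated["final_group"] == "excluded", "exclusion_reason"]
    return CurationReport(
        n_samples=len(curated),
        group_sizes=curated["final_group"].value_counts().to_dict(),
        exclusions_by_reason=reasons.value_counts().to_dict(),
        flagged_suspected_part=sorted(flagged or []),
    )


def apoe_crosstab(metadata: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """ApoE genotype x analysis-group contingency table (counts only)."""
    md = validate_metadata(metadata)
    g = groups if groups is not None else md["dx_at_draw"]
    g = g.reindex(md.index)
    return pd.crosstab(md["apoe"], g)
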