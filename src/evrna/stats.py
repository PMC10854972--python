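"""Normalization, filtering and differential expression at sequence level.

Normalization is the median-of-ratios method: each sample's size factor is
the median, over genes with no zero count in any sample, of that sample's
counts divided by the gene's geometric mean across samples.

The differential-expression test is a deliberately simple negative-binomial
Wald test: per-gene group means on the size-factor-normalized scale, a pooled
method-of-moments dispersion (Var = mu + phi mu^2), and a Wald statistic on
the log2 fold change via the delta method. There is no dispersion shrinkage,
no fold-change shrinkage and no independent filtering, so results will not
numerically match a full shrinkage-based NB pipeline; the contract (filter ->
normalize -> per-sequence test -> Benjamini-Hochberg) is what is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import BIOTYPES, SequenceCountMatrix

_LN2 = np.log(2.0)
_PSEUDO = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (per sample).

    Only genes with strictly positive counts in every sample contribute to
    the reference. Raises if no such gene exists.
    """
    arr = counts.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; filter low-count genes first"
        )
    logs = np.log(arr[allpos])
    geomean = np.exp(logs.mean(axis=1))
    sf = np.median(arr[allpos] / geomean[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    if sf is None:
        sf = size_factors(counts)
    return counts / sf


def filter_expressed(
    counts: pd.DataFrame,
    min_count: float = 10,
    min_frac: float = 0.5,
    strict_frac: bool = False,
) -> pd.Index:
    """Genes with value > ``min_count`` in at least (or, with ``strict_frac``,
    more than) ``min_frac`` of the samples."""
    if counts.shape[1] == 0:
        raise ValueError("empty comparison")
    frac = (counts > min_count).sum(axis=1) / counts.shape[1]
    keep = frac > min_frac if strict_frac else frac >= min_frac
    return counts.index[keep]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN passed through."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


@dataclass
class DEResult:
    """Per-sequence differential expression for one two-group comparison.

    ``table`` columns: base_mean, log2fc, p, padj, filter_kept (bool).
    log2fc is group2 relative to group1.
    """

    table: pd.DataFrame
    comparison: str = ""
    group1: str = ""
    group2: str = ""

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "padj" if adjusted else "p"
        t = self.table
        return t[t[col].notna() & (t[col] < alpha)]


def nb_wald_de(
    counts: pd.DataFrame,
    group1_samples: list[str],
    group2_samples: list[str],
    min_count: float = 10,
    min_frac: float = 0.5,
    sf: pd.Series | None = None,
    comparison: str = "",
) -> DEResult:
    """NB-Wald differential expression of group2 vs group1.

    The expression filter is applied to *raw* counts of the compared samples;
    size factors are computed on the compared samples (unless given). Genes
    failing the filter, or with all-zero counts, get NaN p-values and are
    excluded from the BH denominator.
    """
    g1, g2 = list(group1_samples), list(group2_samples)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    sub = counts[g1 + g2]
    kept = filter_expressed(sub, min_count=min_count, min_frac=min_frac)
    if sf is None:
        sf = size_factors(sub)
    q = sub / sf
    q1, q2 = q[g1].to_numpy(), q[g2].to_numpy()
    n1, n2 = len(g1), len(g2)
    mu1, mu2 = q1.mean(axis=1), q2.mean(axis=1)
    base_mean = q.mean(axis=1).to_numpy()

    # pooled within-group moments on the normalized scale
    ss = ((q1 - mu1[:, None]) ** 2).sum(axis=1) + ((q2 - mu2[:, None]) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ss / max(n1 + n2 - 2, 1)
        mubar = (n1 * mu1 + n2 * mu2) / (n1 + n2)
        phi = np.maximum((s2 - mubar) / np.maximum(mubar, 1e-12) ** 2, 0.0)
        phi = np.maximum(phi, 1e-8)

        inv_sf1 = (1.0 / sf[g1].to_numpy()).sum()
        inv_sf2 = (1.0 / sf[g2].to_numpy()).sum()
        var_mu1 = (mu1 * inv_sf1 + phi * mu1**2 * n1) / n1**2
        var_mu2 = (mu2 * inv_sf2 + phi * mu2**2 * n2) / n2**2

        log2fc = np.log2((mu2 + _PSEUDO) / (mu1 + _PSEUDO))
        var_log2fc = (
            var_mu1 / (mu1 + _PSEUDO) ** 2 + var_mu2 / (mu2 + _PSEUDO) ** 2
        ) / _LN2**2
        z = log2fc / np.sqrt(var_log2fc)
    p = 2.0 * sps.norm.sf(np.abs(z))

    filter_kept = sub.index.isin(kept)
    testable = filter_kept & (mubar > 0)
    p = np.where(testable, p, np.nan)
    log2fc = np.where(mubar > 0, log2fc, 0.0)
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": bh_adjust(p),
            "filter_kept": filter_kept,
        },
        index=sub.index,
    )
    return DEResult(table=table, comparison=comparison)


# ---------------------------------------------------------------------------
# fraction comparison (%CV, detection overlap)

@dataclass
class CVResult:
    cv_a: pd.Series  # %CV per gene, first matrix (e.g. EV)
    cv_b: pd.Series  # %CV per gene, second matrix (e.g. EV-depleted)
    t_stat: float
    p: float
    n_genes: int


def percent_cv(values: pd.DataFrame) -> pd.Series:
    """Per-gene %CV = 100 * sd / mean across samples; zero-mean genes -> NaN."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean.where(mean > 0)
    return cv


def percent_cv_comparison(
    norm_a: pd.DataFrame,
    norm_b: pd.DataFrame,
    min_count: float = 10,
    min_frac: float = 0.5,
) -> CVResult:
    """Compare per-gene %CV distributions between two fractions.

    The expression filter (> ``min_count`` normalized counts in more than
    ``min_frac`` of samples) is applied jointly across both fractions; %CV is
    then computed per fraction and compared with a two-sided Welch t-test.
    """
    joint = pd.concat([norm_a, norm_b], axis=1)
    kept = filter_expressed(joint, min_count=min_count, min_frac=min_frac,
                            strict_frac=True)
    if len(kept) < 2:
        raise ValueError("fewer than 2 genes pass the joint expression filter")
    cv_a = percent_cv(norm_a.loc[kept]).dropna()
    cv_b = percent_cv(norm_b.loc[kept]).dropna()
    t, p = sps.ttest_ind(cv_a, cv_b, equal_var=False)
    return CVResult(cv_a=cv_a, cv_b=cv_b, t_stat=float(t), p=float(p),
                    n_genes=len(kept))


@dataclass
class OverlapResult:
    n_both: int
    n_a_only: int
    n_b_only: int
    per_biotype: pd.DataFrame  # rows biotype, cols both / a_only / b_only
    top_a: pd.Series  # top-N most abundant sequences (summed counts), matrix A
    top_b: pd.Series


def detection_overlap(
    matrix_a: SequenceCountMatrix,
    matrix_b: SequenceCountMatrix,
    top_n: int = 10,
) -> OverlapResult:
    """Partition detected sequences (count > 0 in >= 1 sample) between two
    fractions; matching is by sequence so gene numbering differences between
    the fractions do not matter."""
    det_a = set(matrix_a.sequences[(matrix_a.counts > 0).any(axis=1)])
    det_b = set(matrix_b.sequences[(matrix_b.counts > 0).any(axis=1)])
    both, a_only, b_only = det_a & det_b, det_a - det_b, det_b - det_a

    bt = {}
    for m in (matrix_a, matrix_b):
        for seq, b in zip(m.sequences, m.biotypes):
            bt[seq] = b
    rows = []
    for b in BIOTYPES:
        rows.append(
            {
                "biotype": b,
                "both": sum(1 for s in both if bt[s] == b),
                "a_only": sum(1 for s in a_only if bt[s] == b),
                "b_only": sum(1 for s in b_only if bt[s] == b),
            }
        )
    per_biotype = pd.DataFrame(rows).set_index("biotype")

    def _top(m: SequenceCountMatrix) -> pd.Series:
        tot = m.counts.sum(axis=1)
        return tot.sort_values(ascending=False).head(top_n)

    return OverlapResult(
        n_both=len(both),
        n_a_only=len(a_only),
        n_b_only=len(b_only),
        per_biotype=per_biotype,
        top_a=_top(matrix_a),
        top_b=_top(matrix_b),
    )


# ---------------------------------------------------------------------------
# DE-set concordance

@dataclass
class ConcordanceSummary:
    a_only: list[str]
    b_only: list[str]
    shared: list[str]
    n_concordant: int
    n_discordant: int

    @property
    def fraction_concordant(self) -> float:
        return self.n_concordant / len(self.shared) if self.shared else float("nan")


def concordance_overlap(
    de_a: DEResult, de_b: DEResult, alpha: float = 0.05
) -> ConcordanceSummary:
    """Overlap of significant sets (unadjusted p < alpha) of two comparisons
    against a shared reference group, with fold-change sign concordance."""
    sig_a = set(de_a.significant(alpha).index)
    sig_b = set(de_b.significant(alpha).index)
    shared = sorted(sig_a & sig_b)
    conc = disc = 0
    for g in shared:
        sa = np.sign(de_a.table.loc[g, "log2fc"])
        sb = np.sign(de_b.table.loc[g, "log2fc"])
        if sa == sb:
            conc += 1
        else:
            disc += 1
    return ConcordanceSummary(
        a_only=sorted(sig_a - sig_b),
        b_only=sorted(sig_b - sig_a),
        shared=shared,
        n_concordant=conc,
        n_discordant=disc,
    )
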