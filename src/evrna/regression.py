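"""Logistic-regression benchmark and time-to-conversion trend regression.

The logistic model is the manual-selection counterpart to the elastic net:
the top 10 differentially expressed sequences (by adjusted p-value or by
|log2FC|) feed an unpenalized binomial GLM, evaluated over repeated random
80/20 train/test splits.

The trend regression asks, per sequence, whether expression in converter
samples tracks the time remaining until their diagnosis changed. The time
axis is x = -years_to_conversion (x = -4 means the participant converted four
years after the blood draw), so conversion approaches as x -> 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .stats import DEResult

_MAX_REDRAWS = 100


def select_top10(de: DEResult, by: str = "padj", n: int = 10) -> list[str]:
    """Top-``n`` tested genes by ascending padj or descending |log2FC|.

    Ties are broken by the other criterion, then by gene ID, so the output is
    deterministic. If fewer than ``n`` genes were tested, all are returned
    (with a warning).
    """
    if by not in ("padj", "abs_log2fc"):
        raise ValueError("criterion must be 'padj' or 'abs_log2fc'")
    t = de.table[de.table["p"].notna()].copy()
    t["abs_lfc"] = t["log2fc"].abs()
    if by == "padj":
        t = t.sort_values(["padj", "abs_lfc", "p"],
                          ascending=[True, False, True],
                          kind="stable")
    else:
        t = t.sort_values(["abs_lfc", "padj"], ascending=[False, True], kind="stable")
    if len(t) < n:
        warnings.warn(f"only {len(t)} tested genes available (< {n})")
    return list(t.index[:n])


@dataclass
class LRMResult:
    genes: list[str]
    criterion: str
    coef: np.ndarray
    intercept: float
    mean_accuracy: float
    sd_accuracy: float
    mean_auc: float
    sd_auc: float
    n_repeats: int
    n_nonconverged: int = 0


def fit_evaluate_lrm(
    x: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int = 100,
    test_frac: float = 0.2,
    seed: int = 0,
    criterion: str = "padj",
) -> LRMResult:
    """Repeated-holdout evaluation of an unpenalized binomial GLM.

    ``x``: samples x genes feature table (normalized expression). Features are
    standardized internally for numerical stability; this does not change the
    model class. Perfect-separation fits are bounded by the iteration cap and
    counted in ``n_nonconverged``. Single-class training splits are redrawn.
    """
    xv = x.to_numpy(dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    means, sds = xv.mean(axis=0), xv.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    xv = (xv - means) / sds
    rng = np.random.default_rng(seed)
    n = len(y)
    n_test = max(1, int(round(n * test_frac)))
    accs, aucs = [], []
    n_nc = 0

    def _fit(xt, yt):
        clf = LogisticRegression(C=np.inf, max_iter=500, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(xt, yt)
        return clf, clf.n_iter_[0] >= 500

    for _ in range(n_repeats):
        for _ in range(_MAX_REDRAWS):
            perm = rng.permutation(n)
            test, train = perm[:n_test], perm[n_test:]
            if len(np.unique(y[train])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class training split")
        clf, nc = _fit(xv[train], y[train])
        n_nc += int(nc)
        prob = clf.predict_proba(xv[test])[:, list(clf.classes_).index(1)]
        accs.append(float(((prob >= 0.5).astype(int) == y[test]).mean()))
        if len(np.unique(y[test])) == 2:
            aucs.append(float(roc_auc_score(y[test], prob)))
    clf_full, _ = _fit(xv, y)
    accs, aucs = np.array(accs), np.array(aucs)
    return LRMResult(
        genes=list(x.columns),
        criterion=criterion,
        coef=clf_full.coef_.ravel().copy(),
        intercept=float(clf_full.intercept_[0]),
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_auc=float(aucs.mean()) if len(aucs) else float("nan"),
        sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        n_repeats=n_repeats,
        n_nonconverged=n_nc,
    )


def time_to_conversion_regression(
    expression: pd.DataFrame,
    years_to_conversion: pd.Series,
    r2_min: float = 0.66,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene OLS of expression on x = -years_to_conversion.

    ``expression``: genes x converter-samples (normalized, typically log2
    scale); ``years_to_conversion``: positive years per sample. Returns a
    table with slope (expression units per year), intercept, R^2, two-sided
    slope p-value, and a ``flagged`` column for genes with R^2 >= ``r2_min``
    and p < ``alpha``.
    """
    samples = [s for s in expression.columns if s in years_to_conversion.index]
    if len(samples) < 3:
        raise ValueError("need at least 3 converter samples for the regression")
    yrs = years_to_conversion[samples].to_numpy(dtype=float)
    if (yrs <= 0).any():
        raise ValueError("years_to_conversion must be > 0 for converters")
    xaxis = -yrs
    rows = []
    for gene, vals in expression[samples].iterrows():
        v = vals.to_numpy(dtype=float)
        if np.allclose(v, v[0]):
            rows.append((gene, 0.0, float(v[0]), 0.0, 1.0))
            continue
        res = sps.linregress(xaxis, v)
        rows.append((gene, float(res.slope), float(res.intercept),
                     float(res.rvalue**2), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["gene_id", "slope", "intercept", "r2", "p"])
    out = out.set_index("gene_id")
    out["flagged"] = (out["r2"] >= r2_min) & (out["p"] < alpha)
    return out
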