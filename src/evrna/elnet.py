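"""Three-loop elastic-net classification on DE-preselected sequences.

The procedure, applied to a two-group comparison:

1. **Penalty tuning** — many random 80/20 train/test splits; on each training
   part a cross-validated path fit picks the accuracy-optimal penalty, the
   held-out 20% measures accuracy, and the penalty of the best iteration wins.
2. **Feature selection** — the same resampling at the fixed penalty; the
   nonzero-coefficient features of the best-accuracy iteration are kept.
3. **Performance estimation** — resampling with penalty *and* feature set
   fixed, reporting mean +/- sd of held-out accuracy and ROC AUC.

The best model is finally refit on all samples of the comparison, applied to
every sample for the waterfall display, and used to project held-out samples
(e.g. preclinical converters) that were never seen during training.

The penalized objective matches the usual elastic net for logistic
regression: (1/n) sum(logloss) + lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2).
Feature columns are median-ratio normalized, log2(x+1) transformed, and
standardized before fitting, because penalized fits are scale-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .stats import DEResult, size_factors

_MAX_REDRAWS = 100


@dataclass
class ElasticNetModel:
    """A fitted penalized logistic classifier plus everything needed to score
    new count data with the training-derived transformations."""

    alpha: float
    lam: float
    features: list[str]
    coef: np.ndarray
    intercept: float
    classes: tuple[str, str]  # (class 0, class 1)
    training_samples: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    #: per-gene log geometric means of the training counts (all-nonzero genes
    #: only); the median-ratio pseudo-reference for sizing new samples
    ref_log_geomeans: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        nz = np.flatnonzero(self.coef)
        if len(nz) != len(self.coef):
            # keep only the nonzero-coefficient set
            self.features = [self.features[i] for i in nz]
            self.coef = self.coef[nz]
            self.feature_means = self.feature_means[nz]
            self.feature_sds = self.feature_sds[nz]

    def transform_counts(self, counts: pd.DataFrame) -> np.ndarray:
        """Counts (genes x samples) -> standardized feature matrix
        (samples x features), sized against the training pseudo-reference."""
        missing = [f for f in self.features if f not in counts.index]
        if missing:
            raise KeyError(f"missing feature(s) in count table: {missing[:5]}")
        ref = self.ref_log_geomeans
        common = ref.index.intersection(counts.index)
        if len(common) == 0:
            raise ValueError("no reference genes shared with the count table")
        logc = np.log(counts.loc[common].where(counts.loc[common] > 0))
        ratios = logc.sub(ref[common], axis=0)
        sf = np.exp(ratios.median(axis=0))
        q = counts.loc[self.features] / sf
        x = np.log2(q.T.to_numpy(dtype=float) + 1.0)
        return (x - self.feature_means) / self.feature_sds

    def predict_proba(self, x_std: np.ndarray) -> np.ndarray:
        """Class-1 probability for an already-standardized feature matrix."""
        z = x_std @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict_proba_counts(self, counts: pd.DataFrame) -> pd.Series:
        p = self.predict_proba(self.transform_counts(counts))
        return pd.Series(p, index=counts.columns, name="probability")


@dataclass
class ModelPerformance:
    best_accuracy: float
    mean_accuracy: float
    sd_accuracy: float
    mean_auc: float
    sd_auc: float
    n_iterations: int
    n_auc_excluded: int = 0
    probabilities: pd.Series | None = None  # per-sample, ascending (waterfall)


# ---------------------------------------------------------------------------
# feature preparation

def preselect_features(de: DEResult, alpha_p: float = 0.05) -> list[str]:
    """Sequences with unadjusted p < alpha_p, in stable (table) order."""
    t = de.table
    sel = list(t.index[t["p"].notna() & (t["p"] < alpha_p)])
    if not sel:
        raise ValueError(
            f"no feature has unadjusted p < {alpha_p}; relax the threshold"
        )
    return sel


def feature_matrix(
    counts: pd.DataFrame, features: list[str], sf: pd.Series | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """log2(normalized + 1), standardized per feature.

    Returns (X samples x features, means, sds); zero-variance features get
    sd 1 so they stay inert rather than propagating NaN.
    """
    if sf is None:
        sf = size_factors(counts)
    q = counts.loc[features] / sf
    x = np.log2(q.T + 1.0)
    means = x.mean(axis=0).to_numpy()
    sds = x.std(axis=0, ddof=0).to_numpy()
    sds = np.where(sds > 0, sds, 1.0)
    xs = (x - means) / sds
    return xs, means, sds


# ---------------------------------------------------------------------------
# penalized fits

def _lambda_grid(x: np.ndarray, y: np.ndarray, alpha: float,
                 n_lambda: int = 20, eps: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty path from the smallest all-zero penalty downwards."""
    n = x.shape[0]
    ybar = y.mean()
    grad = x.T @ (y - ybar) / n
    lam_max = np.abs(grad).max() / max(alpha, 1e-3)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def _fit_enet(x: np.ndarray, y: np.ndarray, lam: float, alpha: float,
              clf: LogisticRegression | None = None) -> LogisticRegression:
    n = x.shape[0]
    C = 1.0 / (n * lam)
    if clf is None:
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=alpha,
            C=C,
            max_iter=2000,
            tol=1e-4,
            warm_start=True,
            random_state=0,
        )
    else:
        clf.C = C
    with warnings.catch_warnings():
        # near-unpenalized fits may hit the iteration cap; the bounded fit is
        # exactly what the resampling loops need
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(x, y)
    return clf


def _split(rng: np.random.Generator, n: int, test_frac: float, y: np.ndarray):
    """Random train/test split; redraw (bounded) if training is single-class."""
    n_test = max(1, int(round(n * test_frac)))
    for _ in range(_MAX_REDRAWS):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        if len(np.unique(y[train])) == 2:
            return train, test
    raise RuntimeError("could not draw a two-class training split")


@dataclass
class TuneResult:
    lam: float
    best_accuracy: float
    best_iteration: int


def tune_lambda(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    n_iter: int = 1000,
    test_frac: float = 0.2,
    seed: int = 0,
    n_folds: int = 3,
    n_lambda: int = 15,
) -> TuneResult:
    """Loop 1: per iteration, cross-validate a penalty path on the 80% part,
    score the accuracy-optimal penalty on the 20% part; return the penalty of
    the highest-accuracy iteration (first maximum on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    grid = _lambda_grid(x, y, alpha, n_lambda=n_lambda)
    best_acc, best_lam, best_it = -1.0, grid[0], -1
    n = x.shape[0]
    for it in range(n_iter):
        train, test = _split(rng, n, test_frac, y)
        xt, yt = x[train], y[train]
        # internal K-fold CV over the path (warm-started from large penalty)
        folds = np.array_split(rng.permutation(len(train)), n_folds)
        cv_correct = np.zeros(len(grid))
        cv_total = 0
        for f in folds:
            mask = np.ones(len(train), dtype=bool)
            mask[f] = False
            if len(np.unique(yt[mask])) < 2 or len(f) == 0:
                continue
            clf = None
            for li, lam in enumerate(grid):
                clf = _fit_enet(xt[mask], yt[mask], lam, alpha, clf)
                cv_correct[li] += (clf.predict(xt[f]) == yt[f]).sum()
            cv_total += len(f)
        lam_it = grid[int(np.argmax(cv_correct))] if cv_total else grid[-1]
        clf = _fit_enet(xt, yt, lam_it, alpha)
        acc = float((clf.predict(x[test]) == y[test]).mean())
        if acc > best_acc:
            best_acc, best_lam, best_it = acc, lam_it, it
    return TuneResult(lam=float(best_lam), best_accuracy=best_acc,
                      best_iteration=best_it)


@dataclass
class SelectResult:
    features: list[str]
    best_accuracy: float
    best_iteration: int


def select_features(
    x: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    lam: float,
    alpha: float = 0.5,
    n_iter: int = 1000,
    test_frac: float = 0.2,
    seed: int = 0,
) -> SelectResult:
    """Loop 2: resample at fixed penalty; keep the nonzero-coefficient
    features of the best-accuracy iteration (first maximum on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    best_acc, best_coef, best_it = -1.0, None, -1
    for it in range(n_iter):
        train, test = _split(rng, n, test_frac, y)
        clf = _fit_enet(x[train], y[train], lam, alpha)
        acc = float((clf.predict(x[test]) == y[test]).mean())
        if acc > best_acc:
            best_acc, best_coef, best_it = acc, clf.coef_.ravel().copy(), it
    nz = np.flatnonzero(best_coef)
    features = [feature_names[i] for i in nz]
    return SelectResult(features=features, best_accuracy=best_acc,
                        best_iteration=best_it)


def estimate_performance(
    x: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 0.5,
    n_iter: int = 1000,
    test_frac: float = 0.2,
    seed: int = 0,
) -> ModelPerformance:
    """Loop 3: resample with penalty and feature set fixed (``x`` already
    restricted to the selected features); mean +/- sd of held-out accuracy
    and ROC AUC. Single-class test splits contribute no AUC (counted)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    accs, aucs = [], []
    n_excluded = 0
    for _ in range(n_iter):
        train, test = _split(rng, n, test_frac, y)
        clf = _fit_enet(x[train], y[train], lam, alpha)
        prob = clf.predict_proba(x[test])[:, list(clf.classes_).index(1)]
        accs.append(float(((prob >= 0.5).astype(int) == y[test]).mean()))
        if len(np.unique(y[test])) == 2:
            aucs.append(float(roc_auc_score(y[test], prob)))
        else:
            n_excluded += 1
    accs, aucs = np.array(accs), np.array(aucs)
    return ModelPerformance(
        best_accuracy=float(accs.max()),
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_auc=float(aucs.mean()) if len(aucs) else float("nan"),
        sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        n_iterations=n_iter,
        n_auc_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# end-to-end procedure

def three_loop_elastic_net(
    counts: pd.DataFrame,
    labels: pd.Series,
    group1: str,
    group2: str,
    de: DEResult | None = None,
    alpha: float = 0.5,
    alpha_p: float = 0.05,
    n_iter: int = 1000,
    test_frac: float = 0.2,
    seed: int = 0,
    min_count: float = 10,
    min_frac: float = 0.5,
) -> tuple[ElasticNetModel, ModelPerformance]:
    """Run the full procedure for ``group2`` (class 1) vs ``group1`` (class 0).

    ``labels`` maps sample id -> group; only samples labelled with the two
    groups are used for training. The three loops draw their split streams
    from a single master seed, so the whole procedure is deterministic.
    """
    from .stats import nb_wald_de  # local import to avoid cycle at module load

    samples1 = [s for s in counts.columns if labels.get(s) == group1]
    samples2 = [s for s in counts.columns if labels.get(s) == group2]
    if len(samples1) < 2 or len(samples2) < 2:
        raise ValueError(f"need >= 2 samples per group ({group1}: {len(samples1)}, "
                         f"{group2}: {len(samples2)})")
    sub = counts[samples1 + samples2]
    if de is None:
        de = nb_wald_de(counts, samples1, samples2, min_count=min_count,
                        min_frac=min_frac, comparison=f"{group1}_vs_{group2}")
    features = preselect_features(de, alpha_p=alpha_p)

    sf = size_factors(sub)
    xs, means, sds = feature_matrix(sub, features, sf)
    x = xs.to_numpy(dtype=float)
    y = np.array([0] * len(samples1) + [1] * len(samples2))

    s1, s2, s3 = (int(s.generate_state(1)[0] % (2**31))
                  for s in np.random.SeedSequence(seed).spawn(3))
    tune = tune_lambda(x, y, alpha=alpha, n_iter=n_iter, test_frac=test_frac, seed=s1)
    sel = select_features(x, y, features, tune.lam, alpha=alpha, n_iter=n_iter,
                          test_frac=test_frac, seed=s2)
    if not sel.features:
        raise ValueError("best model has no nonzero coefficients")
    idx = [features.index(f) for f in sel.features]
    perf = estimate_performance(x[:, idx], y, tune.lam, alpha=alpha,
                                n_iter=n_iter, test_frac=test_frac, seed=s3)

    # final model: refit on all comparison samples, restricted feature set
    clf = _fit_enet(x[:, idx], y, tune.lam, alpha)
    arr = sub.to_numpy(dtype=float)
    allpos = (arr > 0).all(axis=1)
    ref = pd.Series(np.log(arr[allpos]).mean(axis=1), index=sub.index[allpos])
    model = ElasticNetModel(
        alpha=alpha,
        lam=tune.lam,
        features=list(sel.features),
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        classes=(group1, group2),
        training_samples=samples1 + samples2,
        feature_means=means[idx],
        feature_sds=sds[idx],
        ref_log_geomeans=ref,
    )
    # waterfall over the training samples
    prob = model.predict_proba(x[:, [features.index(f) for f in model.features]])
    perf.probabilities = pd.Series(prob, index=sub.columns).sort_values()
    return model, perf


def predict_all(model: ElasticNetModel, counts: pd.DataFrame) -> pd.DataFrame:
    """Score every sample; output ordered by ascending probability
    (waterfall order). Classification at the 0.5 cutoff."""
    prob = model.predict_proba_counts(counts).sort_values()
    return pd.DataFrame(
        {
            "probability": prob,
            "assigned_class": np.where(prob >= 0.5, model.classes[1],
                                       model.classes[0]),
        }
    )


def project_new_samples(model: ElasticNetModel, counts_new: pd.DataFrame) -> pd.DataFrame:
    """Project samples unseen during training (e.g. converters) through the
    fitted model; new samples are normalized with size factors computed
    against the training pseudo-reference."""
    overlap = set(counts_new.columns) & set(model.training_samples)
    if overlap:
        raise ValueError(f"samples were used in training: {sorted(overlap)[:3]}")
    out = predict_all(model, counts_new)
    out.attrs["n_assigned"] = {
        c: int((out["assigned_class"] == c).sum()) for c in model.classes
    }
    return out
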