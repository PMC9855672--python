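"""Evaluation protocol: ROC/AUC with DeLong confidence intervals, operating
metrics at a Youden threshold frozen on training data, one-way ANOVA per
feature with significance notation, repeated stratified 70/30 splits, and
lesion-size-threshold stratification.

Labels are −1/+1 throughout; +1 (malignant) is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import SELECTED_FEATURES
from .scoring import DSIModel

SIZE_THRESHOLDS_CM2 = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


# ---- ROC / AUC --------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def roc_auc(scores, labels, ci: bool = True, alpha: float = 0.95):
    """AUC as the Mann–Whitney rank statistic (ties get half credit) and its
    DeLong 95% confidence interval.

    Returns ``(auc, (lo, hi))`` when ``ci`` else the AUC alone.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    if not ci:
        return float(auc)
    # DeLong structural components
    v01 = (all_ranks[:m] - _midrank(pos)) / n
    v10 = 1.0 - (all_ranks[m:] - _midrank(neg)) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    se = np.sqrt(var)
    z = stats.norm.ppf(0.5 + alpha / 2.0)
    lo, hi = np.clip([auc - z * se, auc + z * se], 0.0, 1.0)
    return float(auc), (float(lo), float(hi))


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1 on the
    given (training) scores; midpoints between adjacent scores are scanned."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(scores)
    cand = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_t, best_j = cand[0], -np.inf
    pos = labels == 1
    for t in cand:
        pred = scores >= t
        sens = np.mean(pred[pos]) if pos.any() else np.nan
        spec = np.mean(~pred[~pos]) if (~pos).any() else np.nan
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, t
    return float(best_t)


def operating_metrics(scores, labels, threshold: float) -> dict:
    """Accuracy / sensitivity / specificity at a threshold frozen elsewhere.

    An empty class at evaluation yields NaN for its metric, never a silent 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = np.where(scores >= threshold, 1, -1)
    pos = labels == 1
    neg = ~pos
    sens = float(np.mean(pred[pos] == 1)) if pos.any() else float("nan")
    spec = float(np.mean(pred[neg] == -1)) if neg.any() else float("nan")
    acc = float(np.mean(pred == labels)) if len(labels) else float("nan")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "threshold": float(threshold)}


# ---- per-feature ANOVA ------------------------------------------------------

def significance_notation(p: float) -> str:
    """ns p > 0.05; * p < 0.05; ** p < 0.01; *** p < 0.001; **** p < 0.0001."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_p(values, labels) -> tuple[float, str]:
    """One-way ANOVA p-value across the two label groups, with notation."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need at least two observations per group")
    if all(np.var(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        raise ValueError("zero variance within and between groups; F undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*groups)
    if np.isnan(p):
        p = 1.0 if f == 0 or np.isnan(f) else 0.0
    return float(p), significance_notation(float(p))


# ---- repeated splits --------------------------------------------------------

@dataclass
class SplitPlan:
    """Repeated random train/test partitions (default five 70/30 splits)."""

    n_repeats: int = 5
    train_fraction: float = 0.70
    seeds: tuple = ()
    stratified: bool = True

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must lie in (0, 1)")
        if not self.seeds:
            self.seeds = tuple(range(self.n_repeats))
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("split seeds must be distinct")
        self.n_repeats = len(self.seeds)


def make_splits(labels, plan: SplitPlan | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (stratified) random splits; train and test partition the cohort."""
    if plan is None:
        plan = SplitPlan()
    labels = np.asarray(labels)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if plan.stratified and (len(classes) < 2 or counts.min() < 2):
        raise ValueError("each class needs >= 2 cases for stratified splitting")
    splits = []
    for seed in plan.seeds:
        rng = np.random.default_rng(seed)
        train_idx = []
        if plan.stratified:
            for c in classes:
                idx = np.flatnonzero(labels == c)
                k = int(round(plan.train_fraction * len(idx)))
                k = min(max(k, 1), len(idx) - 1)
                train_idx.append(rng.permutation(idx)[:k])
            train = np.sort(np.concatenate(train_idx))
        else:
            k = int(round(plan.train_fraction * n))
            train = np.sort(rng.permutation(n)[:k])
        test = np.setdiff1d(np.arange(n), train)
        splits.append((train, test))
    return splits


# ---- protocol driver --------------------------------------------------------

COMBINERS = ("pc1", "projection", "svm_distance")


@dataclass
class EvalReport:
    """Per-combiner metrics aggregated over repeated splits."""

    per_split: pd.DataFrame  # rows: (combiner, split, set) metrics
    summary: pd.DataFrame  # mean ± STD over splits per combiner and set
    anova: pd.DataFrame = field(default_factory=pd.DataFrame)


def _agg_summary(per_split: pd.DataFrame) -> pd.DataFrame:
    metrics = ["auc", "accuracy", "sensitivity", "specificity"]
    g = per_split.groupby(["combiner", "set"])[metrics]
    mean, std = g.mean(), g.std(ddof=1)
    out = mean.join(std, lsuffix="_mean", rsuffix="_std").reset_index()
    return out


def evaluate_cohort(
    features: pd.DataFrame,
    labels,
    plan: SplitPlan | None = None,
    selected: tuple = SELECTED_FEATURES,
    combiners: tuple = COMBINERS,
    seed: int = 0,
) -> EvalReport:
    """Train/test the three combined scores over repeated stratified splits.

    All model fitting (standardization, PCA, reference direction, SVM and
    the operating threshold) uses training folds only; test folds are scored
    with frozen parameters.
    """
    if plan is None:
        plan = SplitPlan()
    labels = np.asarray(labels)
    X = features[list(selected)]
    rows = []
    for split_i, (train, test) in enumerate(make_splits(labels, plan)):
        model = DSIModel(feature_names=list(selected), seed=seed).fit(
            X.iloc[train], labels[train]
        )
        for comb in combiners:
            s_train = model.decision_function(X.iloc[train], combiner=comb)
            s_test = model.decision_function(X.iloc[test], combiner=comb)
            thr = youden_threshold(s_train, labels[train])
            for name, s, y in (("train", s_train, labels[train]), ("test", s_test, labels[test])):
                auc, ci95 = roc_auc(s, y)
                rows.append(
                    {
                        "combiner": comb,
                        "split": split_i,
                        "set": name,
                        "auc": auc,
                        "ci_lo": ci95[0],
                        "ci_hi": ci95[1],
                        **operating_metrics(s, y, thr),
                    }
                )
    per_split = pd.DataFrame(rows)
    anova_rows = []
    for feat in features.columns:
        if feat in ("case_id", "label", "area_cm2"):
            continue
        p, note = anova_p(features[feat].to_numpy(), labels)
        anova_rows.append({"feature": feat, "p_value": p, "notation": note})
    return EvalReport(
        per_split=per_split,
        summary=_agg_summary(per_split),
        anova=pd.DataFrame(anova_rows),
    )


def single_feature_aucs(features: pd.DataFrame, labels,
                        names: tuple = SELECTED_FEATURES) -> dict:
    """Orientation-corrected in-sample AUC of each individual feature."""
    labels = np.asarray(labels)
    out = {}
    for name in names:
        v = features[name].to_numpy(dtype=float)
        auc = roc_auc(v, labels, ci=False)
        out[name] = max(auc, 1.0 - auc)
    return out


def size_stratified_eval(
    features: pd.DataFrame,
    labels,
    areas_cm2,
    thresholds=SIZE_THRESHOLDS_CM2,
    plan: SplitPlan | None = None,
    selected: tuple = SELECTED_FEATURES,
    combiners: tuple = ("svm_distance",),
    seed: int = 0,
) -> pd.DataFrame:
    """Re-run the split evaluation keeping only lesions with area > A (strict).

    Rows where a threshold leaves fewer than two cases of either class are
    marked ``insufficient`` instead of being dropped silently.
    """
    labels = np.asarray(labels)
    areas = np.asarray(areas_cm2, dtype=float)
    rows = []
    for thr in thresholds:
        keep = areas > thr
        y = labels[keep]
        counts = [np.sum(y == -1), np.sum(y == 1)]
        if min(counts) < 2:
            rows.append({"size_threshold_cm2": thr, "n_cases": int(keep.sum()),
                         "insufficient": True})
            continue
        rep = evaluate_cohort(
            features.loc[keep].reset_index(drop=True), y, plan=plan,
            selected=selected, combiners=combiners, seed=seed,
        )
        test = rep.summary[rep.summary["set"] == "test"]
        for _, r in test.iterrows():
            rows.append(
                {
                    "size_threshold_cm2": thr,
                    "n_cases": int(keep.sum()),
                    "insufficient": False,
                    "combiner": r["combiner"],
                    "auc_mean": r["auc_mean"],
                    "auc_std": r["auc_std"],
                    "accuracy_mean": r["accuracy_mean"],
                    "sensitivity_mean": r["sensitivity_mean"],
                    "specificity_mean": r["specificity_mean"],
                }
            )
    return pd.DataFrame(rows)
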