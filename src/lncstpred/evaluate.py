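"""Model evaluation: per-class confusion metrics, one-vs-rest ROC/AUC,
F-score feature ranking, stratified cross-validation with in-fold
balancing, and feature-combination ablations.

Multiclass Sn/Sp/MCC are reported per class in one-vs-rest form; the
overall ACC is the single trace/total accuracy. The F-score here is the
feature-selection statistic (between-class over within-class scatter of a
single feature), not the F1 classification metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .balance import BalancingPlan, execute_plan, uncertainty_filter
from .boost import ModifiedAdaBoost


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus the overall accuracy."""

    class_set: list[str]
    confusion: pd.DataFrame
    per_class: pd.DataFrame  # columns TP FN FP TN Sn Sp MCC (+ AUC)
    acc: float
    macro_auc: float | None = None
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"overall ACC = {100 * self.acc:.2f}%"]
        if self.macro_auc is not None:
            lines.append(f"macro AUC = {self.macro_auc:.3f}")
        with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
            lines.append(self.per_class.to_string())
        return "\n".join(lines)


def _binary_mcc(tp: int, fn: int, fp: int, tn: int) -> float:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, class_set: list[str]
) -> MetricsReport:
    """k x k confusion matrix plus per-class one-vs-rest Sn/Sp/MCC and ACC.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP); MCC uses the standard binary formula
    on the one-vs-rest counts, with the 0-denominator convention MCC = 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    if len(y_true) == 0:
        raise ValueError("empty input")
    unknown = set(y_true) | set(y_pred)
    if not unknown <= set(class_set):
        raise ValueError(f"labels outside class_set: {sorted(unknown - set(class_set))}")

    k = len(class_set)
    pos = {c: i for i, c in enumerate(class_set)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[pos[t], pos[p]] += 1
    total = cm.sum()

    rows = []
    for i, c in enumerate(class_set):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = int(total - tp - fn - fp)
        sn = tp / (tp + fn) if tp + fn else 0.0
        sp = tn / (tn + fp) if tn + fp else 0.0
        rows.append(
            {"TP": tp, "FN": fn, "FP": fp, "TN": tn,
             "Sn": sn, "Sp": sp, "MCC": _binary_mcc(tp, fn, fp, tn)}
        )
    per_class = pd.DataFrame(rows, index=class_set)
    confusion = pd.DataFrame(cm, index=class_set, columns=class_set)
    return MetricsReport(
        class_set=list(class_set),
        confusion=confusion,
        per_class=per_class,
        acc=float(np.trace(cm) / total),
    )


def roc_auc(
    y_true: np.ndarray, scores: np.ndarray, class_set: list[str]
) -> tuple[dict[str, float | None], float | None]:
    """One-vs-rest AUC per class plus the macro average.

    AUC is the trapezoidal area under the ROC of the class's score column
    (equivalently the tie-corrected Mann-Whitney statistic). Classes with
    no positives or no negatives have undefined AUC (None) and are excluded
    from the macro average.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(y_true), len(class_set)):
        raise ValueError("scores shape must be (n_samples, n_classes)")
    aucs: dict[str, float | None] = {}
    defined: list[float] = []
    for j, c in enumerate(class_set):
        pos_mask = y_true == c
        if pos_mask.all() or not pos_mask.any():
            aucs[c] = None
            continue
        a = float(roc_auc_score(pos_mask.astype(int), scores[:, j]))
        aucs[c] = a
        defined.append(a)
    macro = float(np.mean(defined)) if defined else None
    return aucs, macro


@dataclass
class FScoreRanking:
    """F statistic per feature with the descending rank order."""

    scores: np.ndarray
    names: list[str]
    order: np.ndarray  # feature indices, best first

    def top(self, n: int) -> list[str]:
        return [self.names[i] for i in self.order[:n]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature": [self.names[i] for i in self.order],
                "F": self.scores[self.order],
            }
        )


def fscore(
    X: np.ndarray, y: np.ndarray, names: list[str] | None = None
) -> FScoreRanking:
    """Feature-selection F-score of each feature.

    F_i = sum_j (mean_ij - mean_i)^2
          / sum_j [ 1/(n_j - 1) * sum_k (x_kij - mean_ij)^2 ]

    where j runs over classes. Every class needs n_j >= 2. A tiny guard
    (1e-12) is added to the denominator only when all within-class
    variances vanish, which maps a between-class-separated constant feature
    to a huge but finite score. Ties in the ranking break by feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 samples: {list(small)}")
    grand = X.mean(axis=0)
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    for c, n_j in zip(classes, counts):
        Xc = X[y == c]
        mu = Xc.mean(axis=0)
        num += (mu - grand) ** 2
        den += ((Xc - mu) ** 2).sum(axis=0) / (n_j - 1)
    den = np.where(den == 0, 1e-12, den)
    F = num / den
    order = np.lexsort((np.arange(len(F)), -F))
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    return FScoreRanking(scores=F, names=list(names), order=order)


# ---------------------------------------------------------------------------
# Cross-validation


def _balance_training_fold(
    X: np.ndarray,
    y: np.ndarray,
    plan: BalancingPlan | None,
    filter_tau: float | None,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    if plan is None:
        return X, y, {}
    samples, log = execute_plan(X, y, plan)
    retained, flog = uncertainty_filter(
        X, y, samples, tau=filter_tau, seed=seed
    )
    if retained:
        Xs = np.vstack([s.features for s in retained])
        ys = np.array([s.cls for s in retained])
        X = np.vstack([X, Xs])
        y = np.concatenate([y, ys])
    return X, y, {"oversampling": log, "filter": flog}


def stratified_kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    plan: BalancingPlan | None = None,
    filter_tau: float | None = None,
    n_rounds: int = 100,
    depth: int = 2,
    seed: int = 0,
) -> tuple[MetricsReport, list[dict]]:
    """Stratified k-fold cross-validation with in-fold balancing.

    Oversampling (when a plan is given) is applied to the TRAINING portion
    of each fold only; held-out folds contain real samples exclusively, so
    synthetic points can never leak into evaluation. Predictions are pooled
    over all folds — each real sample is tested exactly once — and
    summarized in a single report with per-class AUC.

    When the smallest class has fewer members than ``folds``, the fold
    count is reduced to that size (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    class_set = sorted(np.unique(y))
    if len(class_set) < 2:
        raise ValueError("cross-validation needs at least 2 classes")
    min_count = int(np.unique(y, return_counts=True)[1].min())
    if folds > min_count:
        warnings.warn(
            f"reducing folds from {folds} to {min_count} "
            "(smallest class size)", stacklevel=2
        )
        folds = min_count

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled_pred = np.empty(len(y), dtype=y.dtype)
    pooled_scores = np.zeros((len(y), len(class_set)))
    tested = np.zeros(len(y), dtype=bool)
    fold_logs: list[dict] = []
    for f, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        assert not tested[test_idx].any()
        fold_plan = None
        if plan is not None:
            fold_plan = BalancingPlan(
                targets=dict(plan.targets),
                smote_k=plan.smote_k,
                danger_m=plan.danger_m,
                method=dict(plan.method),
                default_method=plan.default_method,
                scale_columns=plan.scale_columns,
                seed=plan.seed + f,
            )
            # targets may exceed what the fold can support; recompute deficits
            # against fold counts but never below the fold's own counts
            fold_counts = dict(zip(*np.unique(y[train_idx], return_counts=True)))
            fold_plan.targets = {
                c: max(t * (folds - 1) // folds, fold_counts.get(c, 0))
                for c, t in plan.targets.items()
            }
        Xtr, ytr, blog = _balance_training_fold(
            X[train_idx], y[train_idx], fold_plan, filter_tau, seed + f
        )
        model = ModifiedAdaBoost(
            n_rounds=n_rounds, depth=depth, seed=seed
        ).fit(Xtr, ytr)
        pooled_pred[test_idx] = model.predict(X[test_idx])
        model_classes = list(model.classes_)
        sc = model.predict_scores(X[test_idx])
        for j, c in enumerate(class_set):
            if c in model_classes:
                pooled_scores[test_idx, j] = sc[:, model_classes.index(c)]
        tested[test_idx] = True
        fr = confusion_metrics(y[test_idx], pooled_pred[test_idx], class_set)
        fold_logs.append({"fold": f, "acc": fr.acc, "balance": blog})
    assert tested.all()

    report = confusion_metrics(y, pooled_pred, class_set)
    aucs, macro = roc_auc(y, pooled_scores, class_set)
    report.per_class["AUC"] = [aucs[c] for c in class_set]
    report.macro_auc = macro
    return report, fold_logs


def ablation(
    frame: pd.DataFrame,
    feature_subsets: dict[str, list[str]],
    folds: int = 10,
    plan: BalancingPlan | None = None,
    n_rounds: int = 100,
    depth: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate each named feature subset and tabulate the results.

    ``frame`` is a featurize-style DataFrame (features + ``label`` column);
    each subset lists manifest column names. The output has one row per
    subset with macro-averaged Sn/Sp/MCC and the overall ACC.
    """
    if len(set(feature_subsets)) != len(feature_subsets):
        raise ValueError("duplicate subset names")
    y = frame["label"].to_numpy()
    rows = []
    for name, cols in feature_subsets.items():
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"subset {name!r}: unknown features {missing[:5]}")
        X = frame[cols].to_numpy(dtype=float)
        sub_plan = plan
        if plan is not None and plan.scale_columns:
            scale = tuple(cols.index("MFE") for _ in ("MFE",) if "MFE" in cols)
            sub_plan = BalancingPlan(
                targets=dict(plan.targets), smote_k=plan.smote_k,
                danger_m=plan.danger_m, method=dict(plan.method),
                default_method=plan.default_method,
                scale_columns=scale, seed=plan.seed,
            )
        report, _ = stratified_kfold_cv(
            X, y, folds=folds, plan=sub_plan,
            n_rounds=n_rounds, depth=depth, seed=seed,
        )
        rows.append(
            {
                "subset": name,
                "Sn": float(report.per_class["Sn"].mean()),
                "Sp": float(report.per_class["Sp"].mean()),
                "ACC": report.acc,
                "MCC": float(report.per_class["MCC"].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("subset")
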