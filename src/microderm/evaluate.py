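"""k-fold cross-validated diagnostic evaluation.

The pipeline is judged the way a diagnostic test is: sensitivity (true
positive rate among melanomas), specificity (true negative rate among benign
lesions), the ROC curve of sensitivity against 1 - specificity, and its
area. Cross-validation refits the scaling and the feature selection inside
every training fold, so no information from a test fold leaks into the
model it is scored against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skmetrics
from sklearn.model_selection import KFold, StratifiedKFold

from .features import FeatureTable, apply_scaling, fit_scaling
from .model import SvmConfig, predict, train
from .select import cfs_search

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "EvalReport",
    "kfold_split",
    "sensitivity",
    "specificity",
    "roc_curve",
    "cross_validate",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_predictions(cls, pred: np.ndarray, truth: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred)
        truth = np.asarray(truth)
        return cls(
            tp=int(np.sum((pred == 1) & (truth == 1))),
            fp=int(np.sum((pred == 1) & (truth == 0))),
            tn=int(np.sum((pred == 0) & (truth == 0))),
            fn=int(np.sum((pred == 0) & (truth == 1))),
        )


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN): the probability a melanoma is called malignant."""
    pos = counts.tp + counts.fn
    if pos == 0:
        raise ValueError("sensitivity undefined: no positive samples")
    return counts.tp / pos


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP): the probability a benign lesion is called benign."""
    neg = counts.tn + counts.fp
    if neg == 0:
        raise ValueError("specificity undefined: no negative samples")
    return counts.tn / neg


@dataclass
class RocCurve:
    points: np.ndarray  # (m, 2) of (1 - specificity, sensitivity)
    auc: float

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            self.points,
            delimiter=",",
            header="fpr,tpr",
            comments="",
        )


def roc_curve(decision_values: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC sweep over the sorted unique decision values with trapezoidal AUC.

    Tied scores cross their threshold simultaneously; the curve is anchored
    at (0, 0) and (1, 1), so constant scores give exactly AUC = 0.5.
    """
    labels = np.asarray(labels)
    scores = np.asarray(decision_values, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    pts = np.column_stack([fpr, tpr])
    if not np.array_equal(pts[0], [0.0, 0.0]):
        pts = np.vstack([[0.0, 0.0], pts])
    if not np.array_equal(pts[-1], [1.0, 1.0]):
        pts = np.vstack([pts, [1.0, 1.0]])
    auc = float(_skmetrics.auc(pts[:, 0], pts[:, 1]))
    return RocCurve(points=pts, auc=auc)


def kfold_split(n: int, k: int, seed: int, labels: np.ndarray) -> np.ndarray:
    """Stratified random fold assignment: fold sizes within 1 of each other,
    per-fold class proportions within 1 sample of the global ones."""
    if not (2 <= k <= n):
        raise ValueError(f"k must satisfy 2 <= k <= n (got k={k}, n={n})")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    # stratification needs at least one member of each class per fold; fall
    # back to a plain shuffled partition for leave-one-out-like settings
    if k <= np.bincount(labels.astype(int)).min():
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((n, 1)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class EvalReport:
    fold_counts: list[ConfusionCounts]
    pooled: ConfusionCounts
    sensitivity: float
    specificity: float
    roc: RocCurve
    selected_subsets: list[tuple[str, ...]] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "folds": [vars(c) for c in self.fold_counts],
            "pooled": vars(self.pooled),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.roc.auc,
            "selected_subsets": [list(s) for s in self.selected_subsets],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def cross_validate(
    table: FeatureTable,
    config: SvmConfig,
    k: int = 10,
    seed: int = 0,
    select: bool = True,
) -> EvalReport:
    """Stratified k-fold CV of the select + scale + SVM chain.

    Within every loop the feature subset (CFS) and the [-1, 1] scaling are
    fitted on the k-1 training folds only and then applied, frozen, to the
    held-out fold. Per-fold confusion counts are summed into pooled counts;
    the ROC pools the held-out decision values of all folds.
    """
    n = len(table.labels)
    assignment = kfold_split(n, k, seed, table.labels)
    fold_counts: list[ConfusionCounts] = []
    subsets: list[tuple[str, ...]] = []
    all_scores = np.empty(n, dtype=float)
    all_pred = np.empty(n, dtype=np.int64)
    for fold in range(k):
        te = np.nonzero(assignment == fold)[0]
        tr = np.nonzero(assignment != fold)[0]
        train_tab = table.take(tr)
        test_tab = table.take(te)
        if select:
            subset = cfs_search(train_tab).subset
        else:
            subset = tuple(train_tab.names)
        subsets.append(subset)
        train_sub = train_tab.subset(subset)
        scaling = fit_scaling(train_sub)
        model = train(
            apply_scaling(train_sub, scaling), config, scaling=scaling, subset=subset
        )
        pred, scores = predict(model, test_tab)
        all_scores[te] = scores
        all_pred[te] = pred
        fold_counts.append(ConfusionCounts.from_predictions(pred, test_tab.labels))
    pooled = sum(fold_counts[1:], fold_counts[0])
    return EvalReport(
        fold_counts=fold_counts,
        pooled=pooled,
        sensitivity=sensitivity(pooled),
        specificity=specificity(pooled),
        roc=roc_curve(all_scores, table.labels),
        selected_subsets=subsets,
    )
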