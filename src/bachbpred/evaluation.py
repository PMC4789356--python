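"""Classifier evaluation: confusion counts, ACC/SN/SP/MCC/FPR, k-fold
cross-validation with per-fold mean ± SD, ROC curves and AUC.

Metrics follow the standard binary definitions on percentages:

    ACC = (TP+TN)/(TP+TN+FP+FN) * 100
    SN  = TP/(TP+FN) * 100          (recall on positives)
    SP  = TN/(TN+FP) * 100          (recall on negatives)
    FPR = FP/(FP+TN) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator is zero is reported as None (undefined) with
a warning, never silently as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from . import svm
from .errors import ValidationError
from .svm import SVMParams, TrainedModel


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; total equals the number of evaluated examples."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricsReport:
    """ACC/SN/SP/FPR as percentages, MCC in [−1, 1]; None = undefined."""

    acc: float | None
    sn: float | None
    sp: float | None
    fpr: float | None
    mcc: float | None
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float | None]:
        return {"ACC": self.acc, "SN": self.sn, "SP": self.sp, "FPR": self.fpr, "MCC": self.mcc}


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Compute ACC, SN, SP, FPR (percent) and MCC from confusion counts."""
    if c.total == 0:
        raise ValidationError("cannot compute metrics on zero examples")

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
            return None
        return 100.0 * num / den

    acc = 100.0 * (c.tp + c.tn) / c.total
    sn = ratio(c.tp, c.tp + c.fn, "SN")
    sp = ratio(c.tn, c.tn + c.fp, "SP")
    fpr = ratio(c.fp, c.fp + c.tn, "FPR")
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        warnings.warn("MCC undefined: zero marginal", stacklevel=2)
        mcc: float | None = None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricsReport(acc=acc, sn=sn, sp=sp, fpr=fpr, mcc=mcc, counts=c)


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    """Tally ±1 truth/prediction pairs into confusion counts."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValidationError("truth and prediction lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == -1) & (yp == -1))),
        fp=int(np.sum((yt == -1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == -1))),
    )


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per example id; fold sizes differ by at most one."""

    folds: dict[str, int]
    k: int
    seed: int

    def ids_in_fold(self, fold: int) -> list[str]:
        return [i for i, f in self.folds.items() if f == fold]


def kfold_split(
    ids: Sequence[str],
    k: int,
    seed: int,
    stratify_by: Mapping[str, str] | None = None,
) -> FoldAssignment:
    """Seeded shuffle followed by round-robin fold assignment.

    With ``stratify_by`` the shuffle and assignment run per class (classes
    in sorted label order) while the round-robin pointer carries across
    classes, so fold sizes still differ by at most one globally.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ids in k-fold split")
    if k < 2:
        raise ValidationError("k must be at least 2")
    if k > len(ids):
        raise ValidationError(f"k={k} exceeds number of examples ({len(ids)})")
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    pointer = 0
    if stratify_by is None:
        groups = [ids]
    else:
        missing = [i for i in ids if i not in stratify_by]
        if missing:
            raise ValidationError(f"ids without stratification label: {missing[:5]}")
        by_class: dict[str, list[str]] = {}
        for i in ids:
            by_class.setdefault(stratify_by[i], []).append(i)
        groups = [by_class[label] for label in sorted(by_class)]
    for group in groups:
        order = rng.permutation(len(group))
        for idx in order:
            folds[group[idx]] = pointer % k
            pointer += 1
    return FoldAssignment(folds=folds, k=k, seed=seed)


@dataclass
class CVSummary:
    """Per-fold metrics plus pooled counts and fold-accuracy mean ± SD."""

    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    mean_acc: float
    sd_acc: float
    models: list[TrainedModel] = field(default_factory=list, repr=False)

    @property
    def fold_accuracies(self) -> list[float]:
        return [r.acc for r in self.fold_reports]


def cross_validate(
    X: np.ndarray,
    y: Sequence[int],
    params: SVMParams,
    ids: Sequence[str] | None = None,
    k: int = 5,
    seed: int = 0,
    scheme: str = "raw",
    stratify: bool = True,
    keep_models: bool = False,
) -> CVSummary:
    """k-fold cross-validation of an RBF-SVM on encoded features.

    Trains k models, scores each held-out fold at threshold 0.0, pools
    the confusion counts for overall metrics, and reports the mean and
    sample standard deviation (n−1) of the per-fold accuracies.
    Stratified splitting is the default so small classes cannot produce
    class-empty folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if ids is None:
        ids = [str(i) for i in range(len(y))]
    ids = list(ids)
    if not (len(ids) == X.shape[0] == y.shape[0]):
        raise ValidationError("ids, features and labels must have equal length")
    strat = {i: str(lbl) for i, lbl in zip(ids, y)} if stratify else None
    assignment = kfold_split(ids, k=k, seed=seed, stratify_by=strat)
    fold_of = np.array([assignment.folds[i] for i in ids])

    fold_reports: list[MetricsReport] = []
    models: list[TrainedModel] = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    for fold in range(k):
        test_mask = fold_of == fold
        train_mask = ~test_mask
        y_train = y[train_mask]
        if len(set(y_train.tolist())) < 2 or not test_mask.any():
            raise ValidationError(
                f"fold {fold} leaves a single-class training set; use stratification"
            )
        model = svm.train(X[train_mask], y_train, params, seed=seed, scheme=scheme)
        scores = svm.decision_scores(model, X[test_mask])
        preds = np.where(scores >= model.threshold, 1, -1)
        counts = confusion_from_predictions(y[test_mask], preds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fold_reports.append(compute_metrics(counts))
        pooled_counts = pooled_counts + counts
        if keep_models:
            models.append(model)
    accs = [r.acc for r in fold_reports]
    mean_acc = float(np.mean(accs))
    sd_acc = float(np.std(accs, ddof=1))
    return CVSummary(
        fold_reports=fold_reports,
        pooled=compute_metrics(pooled_counts),
        mean_acc=mean_acc,
        sd_acc=sd_acc,
        models=models,
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve over all distinct score thresholds plus trapezoidal AUC.

    The curve is swept from the highest threshold down; the AUC equals
    the tie-corrected normalized Mann–Whitney U statistic.  Both ±1
    labels must be present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValidationError("scores and labels lengths differ")
    if set(np.unique(y)) != {-1, 1}:
        raise ValidationError("ROC needs both positive and negative labels")
    fpr, tpr, _ = roc_curve(y, s, pos_label=1, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def multiclass_confusion(
    predictions: Mapping[str, str], truth: Mapping[str, str]
) -> pd.DataFrame:
    """Square actual × predicted count matrix over the union of classes.

    Rows are actual classes, columns predicted classes; row sums equal
    per-class totals, and per-class sensitivity is the diagonal over the
    row sum.
    """
    if not truth:
        raise ValidationError("empty input: no examples to tabulate")
    if set(predictions) != set(truth):
        raise ValidationError("prediction and truth id sets differ")
    classes = sorted(set(truth.values()) | set(predictions.values()))
    matrix = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for rec_id, actual in truth.items():
        matrix.loc[actual, predictions[rec_id]] += 1
    matrix.index.name = "actual"
    matrix.columns.name = "predicted"
    return matrix
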