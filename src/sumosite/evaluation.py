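"""Performance assessment: confusion metrics, repeated CV, ROC/AUC.

Metrics follow the usual confusion-matrix definitions: sensitivity
Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Acc = (TP+TN)/total, and Matthews correlation coefficient

    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)),

with MCC defined as 0 when the denominator vanishes. Cross-validation is
stratified (the positive class is rare — roughly 4% of candidate lysines —
so unstratified folds can lack positives entirely), repeated with fresh
random partitions, and averaged over folds then repeats. ROC curves are
averaged vertically on a fixed false-positive-rate grid, with AUC taken
from the averaged curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    acc: float
    sp: float
    sn: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"acc": self.acc, "sp": self.sp, "sn": self.sn, "mcc": self.mcc}


def confusion_counts(truth: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(truth)
    p = np.asarray(predicted)
    return ConfusionCounts(
        tp=int(np.sum((p == 1) & (t == 1))),
        fp=int(np.sum((p == 1) & (t == 0))),
        tn=int(np.sum((p == 0) & (t == 0))),
        fn=int(np.sum((p == 0) & (t == 1))),
    )


def confusion_metrics(counts: ConfusionCounts) -> EvalMetrics:
    """Acc/Sp/Sn/MCC from confusion counts; 0/0 ratios resolve to 0."""
    tp, fp, tn, fn = (float(x) for x in (counts.tp, counts.fp, counts.tn, counts.fn))
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / np.sqrt(denom) if denom > 0 else 0.0
    return EvalMetrics(acc=acc, sp=sp, sn=sn, mcc=float(mcc))


FitFn = Callable[[pd.DataFrame, np.ndarray], object]
ScoreFn = Callable[[object, pd.DataFrame], np.ndarray]


def _default_score(model: object, X: pd.DataFrame) -> np.ndarray:
    return np.asarray(model.decision_function(X))  # type: ignore[attr-defined]


@dataclass(frozen=True)
class CvResult:
    """Averaged metrics over repeated cross-validation."""

    mean: EvalMetrics
    std: EvalMetrics
    per_repeat: tuple[EvalMetrics, ...]
    auc_mean: float
    roc: "RocCurve"


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[int],
    fit: FitFn,
    n_folds: int = 5,
    repeats: int = 25,
    threshold: float = 0.0,
    seed: int = 0,
    score: ScoreFn = _default_score,
) -> CvResult:
    """Repeated stratified k-fold CV with decision-value scoring.

    Each repeat draws a fresh stratified partition; every fold serves as
    the test set exactly once. Metrics are averaged over folds within a
    repeat, then over repeats; the ROC is averaged vertically across
    repeats (pooling each repeat's out-of-fold decision values).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} instances; use fewer than "
            f"{n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    per_repeat: list[EvalMetrics] = []
    repeat_curves: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=fold_seed)
        fold_metrics = []
        oof_scores = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            model = fit(X.iloc[train_idx], y[train_idx])
            dv = score(model, X.iloc[test_idx])
            oof_scores[test_idx] = dv
            pred = (dv > threshold).astype(int)
            fold_metrics.append(confusion_metrics(confusion_counts(y[test_idx], pred)))
        per_repeat.append(_mean_metrics(fold_metrics))
        repeat_curves.append((oof_scores.copy(), y))
    mean = _mean_metrics(per_repeat)
    std = _std_metrics(per_repeat)
    roc = average_roc(repeat_curves)
    aucs = [roc_auc(s, t).auc for s, t in repeat_curves]
    return CvResult(mean, std, tuple(per_repeat), float(np.mean(aucs)), roc)


def _mean_metrics(ms: Sequence[EvalMetrics]) -> EvalMetrics:
    return EvalMetrics(
        acc=float(np.mean([m.acc for m in ms])),
        sp=float(np.mean([m.sp for m in ms])),
        sn=float(np.mean([m.sn for m in ms])),
        mcc=float(np.mean([m.mcc for m in ms])),
    )


def _std_metrics(ms: Sequence[EvalMetrics]) -> EvalMetrics:
    return EvalMetrics(
        acc=float(np.std([m.acc for m in ms])),
        sp=float(np.std([m.sp for m in ms])),
        sn=float(np.std([m.sn for m in ms])),
        mcc=float(np.std([m.mcc for m in ms])),
    )


def self_consistency(
    X: pd.DataFrame,
    y: Sequence[int],
    fit: FitFn,
    threshold: float = 0.0,
    score: ScoreFn = _default_score,
) -> EvalMetrics:
    """Train on all data and evaluate on the same data (fitting capacity)."""
    y = np.asarray(y)
    model = fit(X, y)
    pred = (score(model, X) > threshold).astype(int)
    return confusion_metrics(confusion_counts(y, pred))


def evaluate_fixed_predictions(truth: Sequence[int], predicted: Sequence[int]) -> EvalMetrics:
    """Metrics for an untrained predictor (e.g. the regex baseline)."""
    return confusion_metrics(confusion_counts(truth, predicted))


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered by FPR, with trapezoidal AUC."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    auc: float
    averaged: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(decision_values: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Threshold-sweep ROC with trapezoidal AUC for one set of scores."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, np.asarray(decision_values, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(tuple(fpr), tuple(tpr), auc)


def average_roc(
    runs: Sequence[tuple[Sequence[float], Sequence[int]]],
    grid_points: int = 101,
) -> RocCurve:
    """Vertically averaged ROC across repeats, AUC from the averaged curve.

    Each repeat's curve is interpolated onto a fixed FPR grid; TPRs are
    averaged pointwise.
    """
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = []
    for scores, labels in runs:
        curve = roc_auc(scores, labels)
        tprs.append(np.interp(grid, curve.fpr, curve.tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    auc = float(np.trapezoid(mean_tpr, grid))
    return RocCurve(tuple(grid), tuple(mean_tpr), auc, averaged=True)


def dataset_accounting(counts: "dict[str, int]") -> pd.DataFrame:
    """Dataset-distribution report: sites and percentage per site class.

    ``counts`` maps class names (e.g. consensus-positive) to site counts;
    percentages are of the total, rounded to 2 decimals for display.
    """
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty dataset")
    return pd.DataFrame(
        {
            "site_class": list(counts),
            "sites": list(counts.values()),
            "percent": [round(100.0 * n / total, 2) for n in counts.values()],
        }
    )


def metrics_table(rows: dict[str, EvalMetrics]) -> pd.DataFrame:
    """Report table (rows: evaluation method; columns: Acc/Sp/Sn/MCC).

    Values are rounded to 2 decimals for display, mirroring the usual
    reporting precision; keep the EvalMetrics objects for full precision.
    """
    return pd.DataFrame(
        {
            "Evaluation Method": list(rows),
            "Accuracy": [round(m.acc, 2) for m in rows.values()],
            "Specificity": [round(m.sp, 2) for m in rows.values()],
            "Sensitivity": [round(m.sn, 2) for m in rows.values()],
            "MCC": [round(m.mcc, 2) for m in rows.values()],
        }
    )
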