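"""ReliefF feature ranking with distance-weighted neighbours.

ReliefF scores each feature by how well it separates an instance from its
nearest neighbours of the other class (misses) relative to its nearest
neighbours of the same class (hits): informative features differ across
nearby misses and agree across nearby hits. Here every instance is sampled,
distances are Manhattan on the scaled feature space, and the k nearest
neighbours in each group receive exponentially decaying rank weights
``exp(-(rank/sigma)^2)`` normalized to sum to one — neighbours closer in
rank count more.

The wrapper :func:`select_feature_count` walks the ranking and picks the
feature count whose top-ranked subset maximizes cross-validated MCC, ties
resolved toward fewer features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import svm_model
from .evaluation import ConfusionCounts, confusion_metrics


@dataclass(frozen=True)
class RankedFeatureList:
    """Features ordered by non-increasing ReliefF merit (rank starts at 1)."""

    features: tuple[str, ...]
    merits: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.features) != len(self.merits):
            raise ValueError("features/merits length mismatch")
        if any(a < b for a, b in zip(self.merits, self.merits[1:])):
            raise ValueError("merits must be non-increasing with rank")

    def top(self, n: int) -> tuple[str, ...]:
        return self.features[:n]

    def rank_of(self, feature: str) -> int:
        return self.features.index(feature) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "merit": self.merits,
            }
        )


@dataclass(frozen=True)
class SelectionCurve:
    """Cross-validated MCC as a function of retained feature count."""

    counts: tuple[int, ...]
    mcc: tuple[float, ...]
    chosen_count: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts, "mcc": self.mcc})


def _rank_weights(k: int, sigma: float) -> np.ndarray:
    w = np.exp(-((np.arange(1, k + 1) / sigma) ** 2))
    return w / w.sum()


def rank_features(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    k_neighbors: int = 10,
    weight_sigma: float = 2.0,
    seed: int | None = None,
) -> RankedFeatureList:
    """Rank features by ReliefF merit.

    ``matrix`` should already be min–max scaled; feature differences are
    nevertheless normalized by the per-feature range so unscaled input
    degrades gracefully. All instances are sampled (deterministically), so
    ``seed`` only matters if subsampling is ever introduced; it is accepted
    for interface stability. Ties in merit are broken by the canonical
    column order of ``matrix``.
    """
    X = matrix.to_numpy(dtype=float)
    y = np.asarray(labels)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("ReliefF needs at least two classes")
    if counts.min() < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors + 1 = {k_neighbors + 1} instances per class"
        )

    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = X / span  # feature diffs become |Xn_i - Xn_j| in [0, 1]

    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    weights = _rank_weights(k_neighbors, weight_sigma)

    merit = np.zeros(p)
    for i in range(n):
        dists = np.abs(Xn - Xn[i]).sum(axis=1)
        dists[i] = np.inf  # exclude self
        for c in classes:
            idx = np.flatnonzero(y == c)
            order = idx[np.argsort(dists[idx], kind="stable")][:k_neighbors]
            diffs = np.abs(Xn[order] - Xn[i])  # (k, p)
            contrib = weights[: len(order), None] * diffs
            if c == y[i]:
                merit -= contrib.sum(axis=0)
            else:
                factor = priors[c] / (1.0 - priors[y[i]])
                merit += factor * contrib.sum(axis=0)
    merit /= n

    order = np.lexsort((np.arange(p), -merit))  # merit desc, column order for ties
    features = tuple(matrix.columns[j] for j in order)
    return RankedFeatureList(features, tuple(float(merit[j]) for j in order))


def _cv_mcc(
    X: pd.DataFrame,
    y: np.ndarray,
    config: "svm_model.SvmConfig",
    folds: int,
    seed: int,
) -> float:
    """Mean MCC over stratified folds for a fixed SVM configuration."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    mccs = []
    for train_idx, test_idx in skf.split(X, y):
        model = svm_model.train(X.iloc[train_idx], y[train_idx], config)
        pred = svm_model.predict(model, X.iloc[test_idx])["label"].to_numpy()
        truth = y[test_idx]
        counts = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (truth == 1))),
            fp=int(np.sum((pred == 1) & (truth == 0))),
            tn=int(np.sum((pred == 0) & (truth == 0))),
            fn=int(np.sum((pred == 0) & (truth == 1))),
        )
        mccs.append(confusion_metrics(counts).mcc)
    return float(np.mean(mccs))


def select_feature_count(
    ranking: RankedFeatureList,
    matrix: pd.DataFrame,
    labels: Sequence[int],
    svm_config: "svm_model.SvmConfig",
    folds: int = 10,
    stride: int = 1,
    seed: int = 0,
) -> SelectionCurve:
    """Pick the retained-feature count maximizing cross-validated MCC.

    Counts ``stride, 2*stride, ...`` plus the full feature count are
    evaluated with a fixed SVM configuration (the grid-search optimum is
    not re-tuned per count). Equal MCC prefers fewer features.
    """
    missing = set(ranking.features) - set(matrix.columns)
    if missing:
        raise ValueError(f"ranking references absent features: {sorted(missing)}")
    y = np.asarray(labels)
    p = len(ranking.features)
    counts = sorted(set(range(stride, p + 1, stride)) | {p})
    mccs = []
    for c in counts:
        sub = matrix[list(ranking.top(c))]
        mccs.append(_cv_mcc(sub, y, svm_config, folds, seed))
    best = max(zip(mccs, [-c for c in counts]))  # max MCC, then fewest features
    chosen = -best[1]
    return SelectionCurve(tuple(counts), tuple(mccs), chosen)
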