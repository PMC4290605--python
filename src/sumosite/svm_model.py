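"""Weighted RBF-SVM training, grid search with border extension, prediction.

The classifier is a radial-basis-function SVM with per-class penalty
weights: the positive (sumoylated) class is up-weighted 1:5 by default so
the effective penalty becomes ``weight * C``, counteracting the roughly
1:20 class imbalance without resampling. Hyperparameters (C, gamma) come
from a doubling grid — C over 2^-5..2^15, gamma over 2^-15..2^3 — scored
by cross-validated MCC; when the optimum lands on a grid border the grid
is extended stepwise, at most 5 exponent steps beyond either original
margin.

Predictions act on raw decision values (no probability calibration):
larger values mean more confidently positive, and the named thresholds
low/medium/high = -0.5/0/0.5 trade sensitivity against specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import confusion_counts, confusion_metrics
from .feature_encoding import ScalingParams

#: Named decision-value cutoffs.
THRESHOLDS: dict[str, float] = {"low": -0.5, "medium": 0.0, "high": 0.5}


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters, class weights and decision thresholds."""

    C: float = 1.0
    gamma: float = 0.1
    class_weights: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 5.0}
    )
    thresholds: Mapping[str, float] = field(default_factory=lambda: dict(THRESHOLDS))

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")
        t = self.thresholds
        if not (t["low"] < t["medium"] < t["high"]):
            raise ValueError("thresholds must satisfy low < medium < high")

    def resolve_threshold(self, threshold: str | float) -> float:
        if isinstance(threshold, str):
            if threshold not in self.thresholds:
                raise KeyError(
                    f"unknown threshold {threshold!r}; use one of "
                    f"{sorted(self.thresholds)} or a numeric value"
                )
            return float(self.thresholds[threshold])
        return float(threshold)

    def to_dict(self) -> dict:
        return {
            "C": self.C,
            "gamma": self.gamma,
            "class_weights": {str(k): v for k, v in self.class_weights.items()},
            "thresholds": dict(self.thresholds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmConfig":
        return cls(
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            class_weights={int(k): float(v) for k, v in d["class_weights"].items()},
            thresholds={k: float(v) for k, v in d["thresholds"].items()},
        )


@dataclass(frozen=True)
class GridSpec:
    """Doubling grid over C and gamma exponents, with extension allowance."""

    c_exponents: tuple[int, ...] = tuple(range(-5, 16))
    gamma_exponents: tuple[int, ...] = tuple(range(-15, 4))
    max_extension: int = 5
    step: int = 1

    @property
    def n_points(self) -> int:
        return len(self.c_exponents) * len(self.gamma_exponents)


@dataclass(frozen=True)
class TrainedModel:
    """A fitted decision function plus the metadata needed to reuse it."""

    svc: SVC
    feature_names: tuple[str, ...]
    config: SvmConfig
    seed: int | None = None
    scaler: ScalingParams | None = None

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        self._check_features(X)
        return np.asarray(self.svc.decision_function(X.to_numpy(dtype=float)))

    def _check_features(self, X: pd.DataFrame) -> None:
        if tuple(X.columns) != self.feature_names:
            missing = set(self.feature_names) - set(X.columns)
            extra = set(X.columns) - set(self.feature_names)
            raise ValueError(
                f"feature mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
            )


def train(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    config: SvmConfig,
    seed: int | None = None,
    scaler: ScalingParams | None = None,
) -> TrainedModel:
    """Fit the weighted RBF-SVM; class c trains with penalty weight_c * C."""
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    y = np.asarray(labels)
    svc = SVC(
        kernel="rbf",
        C=config.C,
        gamma=config.gamma,
        class_weight=dict(config.class_weights),
        random_state=seed,
    )
    svc.fit(X, y)
    return TrainedModel(svc, tuple(matrix.columns), config, seed, scaler)


def predict(
    model: TrainedModel,
    matrix: pd.DataFrame,
    threshold: str | float = "medium",
) -> pd.DataFrame:
    """Decision values and thresholded labels for each row.

    The label is positive (1) iff the decision value exceeds the threshold;
    the raw decision value is reported alongside.
    """
    cutoff = model.config.resolve_threshold(threshold)
    dv = model.decision_function(matrix)
    return pd.DataFrame(
        {"decision_value": dv, "label": (dv > cutoff).astype(int)},
        index=matrix.index,
    )


def _cv_mcc_objective(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    config_base: SvmConfig,
    folds: int,
    seed: int,
) -> Callable[[float, float], float]:
    X = matrix
    y = labels

    def objective(C: float, gamma: float) -> float:
        cfg = replace(config_base, C=C, gamma=gamma)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        mccs = []
        for train_idx, test_idx in skf.split(X, y):
            if len(np.unique(y[train_idx])) < 2:
                raise ValueError("degenerate fold: a training fold has one class")
            model = train(X.iloc[train_idx], y[train_idx], cfg)
            pred = predict(model, X.iloc[test_idx], "medium")["label"].to_numpy()
            mccs.append(
                confusion_metrics(confusion_counts(y[test_idx], pred)).mcc
            )
        return float(np.mean(mccs))

    return objective


def grid_search(
    matrix: pd.DataFrame,
    labels: Sequence[int],
    grid: GridSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    config_base: SvmConfig | None = None,
    objective: Callable[[float, float], float] | None = None,
) -> SvmConfig:
    """(C, gamma) maximizing cross-validated MCC over the doubling grid.

    If the argmax sits on a grid border, the bordering axis is extended one
    exponent step at a time, never more than ``grid.max_extension`` steps
    past the original margins, and the search repeats. Ties prefer smaller
    (C, gamma) exponents. ``objective`` may be injected for testing; the
    default is stratified CV MCC at the medium threshold.
    """
    grid = grid or GridSpec()
    base = config_base or SvmConfig()
    y = np.asarray(labels)
    if objective is None:
        if len(np.unique(y)) < 2:
            raise ValueError("grid search needs both classes present")
        objective = _cv_mcc_objective(matrix, y, base, folds, seed)

    c_exp = sorted(grid.c_exponents)
    g_exp = sorted(grid.gamma_exponents)
    c_lo_limit = c_exp[0] - grid.max_extension
    c_hi_limit = c_exp[-1] + grid.max_extension
    g_lo_limit = g_exp[0] - grid.max_extension
    g_hi_limit = g_exp[-1] + grid.max_extension

    scores: dict[tuple[int, int], float] = {}
    while True:
        for ce in c_exp:
            for ge in g_exp:
                if (ce, ge) not in scores:
                    scores[(ce, ge)] = objective(2.0**ce, 2.0**ge)
        # argmax; ties prefer smaller exponents
        best = max(scores.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
        (bc, bg), _ = best
        extended = False
        if bc == c_exp[0] and c_exp[0] - grid.step >= c_lo_limit:
            c_exp.insert(0, c_exp[0] - grid.step)
            extended = True
        elif bc == c_exp[-1] and c_exp[-1] + grid.step <= c_hi_limit:
            c_exp.append(c_exp[-1] + grid.step)
            extended = True
        if bg == g_exp[0] and g_exp[0] - grid.step >= g_lo_limit:
            g_exp.insert(0, g_exp[0] - grid.step)
            extended = True
        elif bg == g_exp[-1] and g_exp[-1] + grid.step <= g_hi_limit:
            g_exp.append(g_exp[-1] + grid.step)
            extended = True
        if not extended:
            return replace(base, C=2.0**bc, gamma=2.0**bg)


# ---------------------------------------------------------------------------
# Serialization: a model bundle directory (model + scaler + config + seed)
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.svc, path / "svc.joblib")
    meta = {
        "feature_names": list(model.feature_names),
        "config": model.config.to_dict(),
        "seed": model.seed,
        "scaler": model.scaler.to_dict() if model.scaler else None,
        "solver": {
            "library": "scikit-learn SVC (libsvm)",
            "shrinking": bool(model.svc.shrinking),
            "tol": float(model.svc.tol),
            "cache_size": float(model.svc.cache_size),
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    return TrainedModel(
        svc=joblib.load(path / "svc.joblib"),
        feature_names=tuple(meta["feature_names"]),
        config=SvmConfig.from_dict(meta["config"]),
        seed=meta["seed"],
        scaler=ScalingParams.from_dict(meta["scaler"]) if meta["scaler"] else None,
    )
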