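"""Per-feature statistical screening of sumoylation windows.

Three comparison strategies are run feature-by-feature:

1. positive vs negative windows,
2. consensus-positive vs non-consensus-positive windows,
3. consensus-negative vs non-consensus-negative windows.

Binary features get a Pearson chi-square test of independence on the 2x2
presence table, with Yates' continuity correction applied only when some
observed cell is below 5. Real-valued features get a two-tailed
Mann-Whitney U test; alongside the U statistic the probability of
superiority PS = U/(n1*n2) and the normal approximation

    z = (U - n1*n2/2) / sqrt(n1*n2*(n1+n2+1)/12)

are reported (no tie correction in z; a tie-corrected variant is available
behind a flag). Within each strategy, p-values are Benjamini-Hochberg
adjusted and flagged at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

from .feature_encoding import BINARY_FEATURES, FEATURE_NAMES

logger = logging.getLogger(__name__)

STRATEGIES = ("pos_vs_neg", "cons_pos_vs_noncons_pos", "cons_neg_vs_noncons_neg")

ALPHA = 0.05


class UntestableError(ValueError):
    """Raised when a contingency table cannot support a chi-square test."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Observed counts; rows = groups, columns = feature present/absent."""

    o11: int
    o12: int
    o21: int
    o22: int

    def __post_init__(self) -> None:
        if min(self.o11, self.o12, self.o21, self.o22) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def observed(self) -> np.ndarray:
        return np.array([[self.o11, self.o12], [self.o21, self.o22]], dtype=float)

    @property
    def n(self) -> int:
        return self.o11 + self.o12 + self.o21 + self.o22


def chi2_independence(table: ContingencyTable2x2) -> tuple[float, float, bool]:
    """Pearson chi-square (df = 1) with the observed-cell Yates rule.

    Returns (statistic, p, corrected). Yates' continuity correction — the
    observed counts are moved toward expectation by at most 0.5 — is
    applied iff any observed cell is below 5. A zero row or column margin
    makes the test undefined and raises :class:`UntestableError`.
    """
    obs = table.observed
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if rows.min() == 0:
        raise UntestableError("a group is empty")
    if cols.min() == 0:
        raise UntestableError("feature constant across both groups")
    expected = np.outer(rows, cols) / table.n
    corrected = bool(obs.min() < 5)
    diff = np.abs(obs - expected)
    if corrected:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(chi2_dist.sf(statistic, df=1))
    return statistic, p, corrected


@dataclass(frozen=True)
class MannWhitneyResult:
    """Mann-Whitney U oriented to the positive (first) group."""

    u: float
    n1: int
    n2: int
    ps: float
    z: float
    p: float

    def __post_init__(self) -> None:
        if not 0 <= self.u <= self.n1 * self.n2:
            raise ValueError("U outside [0, n1*n2]")
        if not 0.0 <= self.ps <= 1.0:
            raise ValueError("PS outside [0, 1]")


def mann_whitney(
    group_pos: Sequence[float],
    group_neg: Sequence[float],
    tie_correction: bool = False,
) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U with PS and z statistics.

    U is computed by the midrank method and oriented to the first group,
    so PS = U/(n1*n2) estimates P(positive value > negative value) with
    ties counted half. By default z carries no tie correction; set
    ``tie_correction=True`` for the tie-adjusted variance.
    """
    x = np.asarray(group_pos, dtype=float)
    y = np.asarray(group_neg, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    r1 = ranks[:n1].sum()
    u = float(r1 - n1 * (n1 + 1) / 2)
    ps = u / (n1 * n2)
    var = n1 * n2 * (n1 + n2 + 1) / 12.0
    if tie_correction:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        var -= n1 * n2 * ((tie_counts**3 - tie_counts).sum()) / (12.0 * n * (n - 1))
    z = (u - n1 * n2 / 2.0) / np.sqrt(var) if var > 0 else 0.0
    p = min(1.0, float(2.0 * norm.sf(abs(z))))
    return MannWhitneyResult(u=u, n1=n1, n2=n2, ps=ps, z=float(z), p=p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    adj_(i) = min over j >= i of p_(j) * m / j, capped at 1, where p_(1..m)
    are the sorted raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def _binary_result(feature: str, g1: np.ndarray, g2: np.ndarray) -> dict:
    present1, present2 = int((g1 == 1).sum()), int((g2 == 1).sum())
    table = ContingencyTable2x2(
        present1, len(g1) - present1, present2, len(g2) - present2
    )
    row = {
        "feature": feature,
        "test": "chi2",
        "group1_stat": present1 / len(g1),
        "group2_stat": present2 / len(g2),
        "statistic": np.nan,
        "p": np.nan,
        "untestable": False,
    }
    try:
        stat, p, corrected = chi2_independence(table)
    except UntestableError:
        row["untestable"] = True
        return row
    row.update(statistic=stat, p=p, test="chi2_yates" if corrected else "chi2")
    return row


def _real_result(feature: str, g1: np.ndarray, g2: np.ndarray) -> dict:
    res = mann_whitney(g1, g2)
    return {
        "feature": feature,
        "test": "mannwhitney",
        "group1_stat": float(np.mean(g1)),
        "group2_stat": float(np.mean(g2)),
        "group1_sd": float(np.std(g1, ddof=1)) if len(g1) > 1 else 0.0,
        "group2_sd": float(np.std(g2, ddof=1)) if len(g2) > 1 else 0.0,
        "statistic": res.u,
        "PS": res.ps,
        "Z": res.z,
        "p": res.p,
        "untestable": False,
    }


def run_comparisons(
    dataset: pd.DataFrame,
    strategies: Sequence[str] = STRATEGIES,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Run the per-feature screening for each comparison strategy.

    ``dataset`` is an encoded matrix with ``label`` metadata and the raw
    (unscaled) feature columns; consensus grouping uses the Consensus
    feature column. One test per available feature per strategy; features
    constant across both groups yield explicit untestable rows. BH
    adjustment is applied within each strategy's family of testable
    p-values.
    """
    labels = dataset["label"].map({"positive": 1, "negative": 0})
    if labels.isna().any():
        raise ValueError("dataset labels must be 'positive' or 'negative'")
    consensus = dataset["Consensus"].astype(int)
    features = [f for f in FEATURE_NAMES if f in dataset.columns]

    masks = {
        "pos_vs_neg": (labels == 1, labels == 0),
        "cons_pos_vs_noncons_pos": (
            (labels == 1) & (consensus == 1),
            (labels == 1) & (consensus == 0),
        ),
        "cons_neg_vs_noncons_neg": (
            (labels == 0) & (consensus == 1),
            (labels == 0) & (consensus == 0),
        ),
    }

    frames = []
    for strategy in strategies:
        mask1, mask2 = masks[strategy]
        if mask1.sum() == 0 or mask2.sum() == 0:
            logger.warning("strategy %s skipped: an empty group", strategy)
            continue
        rows = []
        for feature in features:
            g1 = dataset.loc[mask1, feature].to_numpy(dtype=float)
            g2 = dataset.loc[mask2, feature].to_numpy(dtype=float)
            if feature in BINARY_FEATURES:
                rows.append(_binary_result(feature, g1.astype(int), g2.astype(int)))
            else:
                rows.append(_real_result(feature, g1, g2))
        frame = pd.DataFrame(rows)
        frame.insert(0, "strategy", strategy)
        testable = ~frame["untestable"]
        frame["p_adj"] = np.nan
        frame.loc[testable, "p_adj"] = bh_adjust(frame.loc[testable, "p"].to_numpy())
        frame["significant"] = frame["p_adj"] < alpha
        frames.append(frame)
    if not frames:
        raise ValueError("no strategy could be evaluated")
    return pd.concat(frames, ignore_index=True)
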