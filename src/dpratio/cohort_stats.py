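"""Cohort-level evaluation of the 90th DP ratio as a detection score.

Welch's unequal-variance t-test compares labeled groups, ROC analysis
sweeps the score threshold (a case is called positive when its score is
at or above the threshold), operating points are picked at a minimum
sensitivity or specificity of 90%, and the three-group comparison
(both findings / duct dilation only / neither) applies a Bonferroni
correction at alpha/3.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, roc_curve

__all__ = [
    "CohortTable",
    "WelchResult",
    "RocResult",
    "OperatingPoint",
    "welch_t_test",
    "roc_auroc",
    "select_thresholds",
    "three_group_comparison",
]


@dataclasses.dataclass
class CohortTable:
    """Per-case scores with binary imaging-finding labels."""

    table: pd.DataFrame  # columns: case_id, score, mpdd, ppa

    def __post_init__(self) -> None:
        df = self.table
        required = {"case_id", "score", "mpdd", "ppa"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if df["case_id"].duplicated().any():
            raise ValueError("case_ids must be unique")
        scores = df["score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(scores)) or np.any(scores < 0):
            raise ValueError("scores must be finite and nonnegative")

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        return cls(pd.DataFrame(records, columns=["case_id", "score", "mpdd", "ppa"]))

    def scores(self, mask=None) -> np.ndarray:
        df = self.table if mask is None else self.table[mask]
        return df["score"].to_numpy(dtype=float)

    def save(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "CohortTable":
        df = pd.read_csv(path)
        df["mpdd"] = df["mpdd"].astype(bool)
        df["ppa"] = df["ppa"].astype(bool)
        return cls(df)


@dataclasses.dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def welch_t_test(group_a, group_b) -> WelchResult:
    """Two-sided Welch's t-test with Welch–Satterthwaite degrees of freedom.

    Degenerate contract: two groups with zero variance and equal means
    compare as indistinguishable (t = 0, p = 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        raise ValueError("both groups have zero variance with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclasses.dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auroc: float


def roc_auroc(scores, labels) -> RocResult:
    """ROC over all distinct score thresholds (score >= threshold is a
    positive call) and its area, which equals the pairwise concordance
    probability (ties counted half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels.astype(int), scores)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds,
                     auroc=float(auc(fpr, tpr)))


@dataclasses.dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    attained: bool  # whether the requested minimum rate was reachable


def _operating_points(scores, labels) -> list[OperatingPoint]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    points = []
    for thr in np.unique(scores):
        called = scores >= thr
        sens = float((called & labels).sum()) / n_pos
        spec = float((~called & ~labels).sum()) / n_neg
        points.append(OperatingPoint(float(thr), sens, spec, True))
    return points


def select_thresholds(scores, labels, min_rate: float = 0.90
                      ) -> tuple[OperatingPoint, OperatingPoint]:
    """Operating points at a sensitivity floor and a specificity floor.

    Returns ``(point_sens, point_spec)``: the threshold with sensitivity
    >= min_rate maximizing specificity, and the threshold with
    specificity >= min_rate maximizing sensitivity.  Ties prefer the
    larger threshold (more conservative positive calls).  When no
    threshold attains the floor, the best attainable point is returned
    flagged ``attained=False``.
    """
    points = _operating_points(scores, labels)

    def pick(primary, secondary):
        feasible = [p for p in points if getattr(p, primary) >= min_rate]
        if feasible:
            best = max(feasible, key=lambda p: (getattr(p, secondary), p.threshold))
            return dataclasses.replace(best, attained=True)
        best = max(points, key=lambda p: (getattr(p, primary),
                                          getattr(p, secondary), p.threshold))
        return dataclasses.replace(best, attained=False)

    return pick("sensitivity", "specificity"), pick("specificity", "sensitivity")


def three_group_comparison(cohort: CohortTable, alpha: float = 0.05) -> dict:
    """Pairwise Welch tests between (MPDD+PPA), (MPDD only), (neither),
    Bonferroni-corrected at alpha / 3."""
    df = cohort.table
    groups = {
        "mpdd_ppa": df[df["mpdd"] & df["ppa"]],
        "mpdd_only": df[df["mpdd"] & ~df["ppa"]],
        "neither": df[~df["mpdd"] & ~df["ppa"]],
    }
    for name, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"group '{name}' has fewer than 2 cases")
    corrected = alpha / 3.0
    out = {"corrected_alpha": corrected, "comparisons": {}}
    names = list(groups)
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = names[i], names[j]
            res = welch_t_test(groups[a]["score"], groups[b]["score"])
            out["comparisons"][f"{a}_vs_{b}"] = {
                "t": res.t, "df": res.df, "p": res.p,
                "significant": res.p < corrected,
            }
    return out
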