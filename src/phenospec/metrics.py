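"""Evaluation of out-of-fold probability scores against binary labels.

Covers the ROC curve and its area (AUC), thresholded accuracy at 0.5, the
classification-adapted a20-index, the Youden-J optimal operating threshold,
a two-sample t-test of score separation between the actual classes, and
selection of lab-confirmed high-confidence samples.

Conventions (frozen):

- positive class = 1 = 'normal-to-high';
- ROC decision rule: predict positive iff score ≥ threshold, thresholds
  swept over the unique observed scores plus a +inf sentinel;
- accuracy rule: predict 1 iff score > 0.5 (strict);
- a20-index: m20/n with m20 = #{label 0, score ≤ 0.2} + #{label 1,
  score ≥ 0.8}, both boundaries inclusive;
- Youden threshold: maximizer of J(t) = TPR(t) − FPR(t), ties broken to
  the smallest threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ValidationError

__all__ = [
    "MetricsReport",
    "roc_auc",
    "accuracy_at_half",
    "a20_index",
    "youden_optimal_threshold",
    "score_group_test",
    "high_confidence_table",
]


@dataclass
class MetricsReport:
    """Headline metrics of one evaluated cohort."""

    auc: float
    accuracy: float
    a20: float
    roc: np.ndarray  # (m, 3) array of (fpr, tpr, threshold), fpr/tpr non-decreasing
    youden_threshold: float
    youden_j: float
    group_t: tuple[float, float]
    high_confidence_counts: dict[float, dict[int, int]] = field(default_factory=dict)
    per_repetition_auc: list[float] = field(default_factory=list)
    per_fold_accuracy: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "a20": self.a20,
            "youden_threshold": self.youden_threshold,
            "youden_j": self.youden_j,
            "group_t": list(self.group_t),
            "high_confidence_counts": {
                str(thr): {str(c): n for c, n in counts.items()}
                for thr, counts in self.high_confidence_counts.items()
            },
            "per_repetition_auc": self.per_repetition_auc,
            "per_fold_accuracy": self.per_fold_accuracy,
            "roc": self.roc.tolist(),
        }


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be aligned 1-D arrays")
    if not np.all(np.isfinite(s)):
        raise ValidationError("non-finite scores")
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("labels must be 0/1")
    return s, y


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve and trapezoidal AUC.

    Returns an (m, 3) array of (fpr, tpr, threshold) ordered from (0, 0)
    to (1, 1) — thresholds descending from the +inf sentinel — plus the
    trapezoidal area under the curve.
    """
    s, y = _validate(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    roc = np.column_stack([fpr, tpr, thr])
    return roc, auc


def accuracy_at_half(scores, labels) -> float:
    """Accuracy with the strict rule: predict 1 iff score > 0.5."""
    s, y = _validate(scores, labels)
    pred = (s > 0.5).astype(int)
    return float(np.mean(pred == y))


def a20_index(scores, labels) -> float:
    """m20/n, counting confidently correct predictions.

    m20 = #{label 0 with score ≤ 0.2} + #{label 1 with score ≥ 0.8};
    both boundaries inclusive.
    """
    s, y = _validate(scores, labels)
    if len(s) == 0:
        raise ValidationError("need at least one sample")
    m20 = int(np.sum((y == 0) & (s <= 0.2)) + np.sum((y == 1) & (s >= 0.8)))
    return m20 / len(s)


def youden_optimal_threshold(roc: np.ndarray) -> tuple[float, float]:
    """Threshold maximizing J = TPR − FPR; ties break to the smallest.

    ``roc`` is the (fpr, tpr, threshold) array from :func:`roc_auc`.
    """
    roc = np.asarray(roc, dtype=float)
    if roc.ndim != 2 or roc.shape[1] != 3 or len(roc) == 0:
        raise ValidationError("roc must be a non-empty (m, 3) array")
    j = roc[:, 1] - roc[:, 0]
    best_j = j.max()
    candidates = roc[j == best_j, 2]
    return float(candidates.min()), float(best_j)


def score_group_test(scores, labels) -> tuple[float, float]:
    """Welch two-sample t-test of scores grouped by actual label.

    Returns (t, two-sided p); t is oriented as class-1 minus class-0.
    """
    s, y = _validate(scores, labels)
    g1, g0 = s[y == 1], s[y == 0]
    if len(g0) < 2 or len(g1) < 2:
        raise ValidationError("need at least 2 samples per class")
    if g0.std(ddof=1) == 0 and g1.std(ddof=1) == 0:
        raise ValidationError("degenerate groups: zero variance in both classes")
    t, p = stats.ttest_ind(g1, g0, equal_var=False)
    return float(t), float(p)


def high_confidence_table(
    scores: dict[str, float],
    labels: dict[str, int],
    tpc: dict[str, float],
    cuts: dict[str, int],
    score_min: float,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Lab-confirmed high-confidence samples at a score threshold.

    Keeps samples with ``score ≥ score_min`` whose laboratory label is 1
    (normal-to-high), sorted by score descending.  Returns the table
    (sample_id, score, tpc, cut) and the per-cut row counts.
    """
    ids = list(scores)
    missing = [i for i in ids if i not in labels or i not in tpc or i not in cuts]
    if missing:
        raise ValidationError(f"unaligned inputs for samples: {missing[:5]}")
    rows = [
        {"sample_id": i, "score": scores[i], "tpc": tpc[i], "cut": cuts[i]}
        for i in ids
        if labels[i] == 1 and scores[i] >= score_min
    ]
    table = pd.DataFrame(rows, columns=["sample_id", "score", "tpc", "cut"])
    table = table.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    counts = table["cut"].value_counts().to_dict() if len(table) else {}
    return table, {int(c): int(n) for c, n in counts.items()}
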