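"""Evaluation statistics: ROC/AUC, accuracy-optimal threshold, Pearson
correlation and Mood's median test.

Conventions (they matter at small n): the empirical ROC is integrated by
the trapezoidal rule, which makes the AUC identical to the Mann–Whitney
probability U/(n₁·n₀) with ties weighted ½; the decision rule is
"positive if score > threshold" and the accuracy-optimal threshold is the
smallest maximizer over all midpoints between sorted unique scores plus
±∞; Mood's test splits at the pooled grand median, counts values equal to
the median as ≤, and uses the 1-df chi-square without continuity
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import DomainError


@dataclass(frozen=True)
class RocResult:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), sorted
    auc: float
    best_threshold: float
    correctly_classified_ratio: float


def _check_two_classes(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.all(np.isin(classes, (0, 1))):
        raise DomainError("labels must be binary 0/1")
    if classes.size != 2:
        raise DomainError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC curve, trapezoidal AUC and accuracy-optimal threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise DomainError("scores and labels must have equal length")
    _check_two_classes(y)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    thr, ratio = best_threshold_by_accuracy(s, y)
    return RocResult(
        points=tuple(zip(map(float, fpr), map(float, tpr))),
        auc=auc,
        best_threshold=thr,
        correctly_classified_ratio=ratio,
    )


def best_threshold_by_accuracy(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float]:
    """Smallest threshold maximizing accuracy of "positive if score > t"."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y)
    uniq = np.unique(s)
    candidates = np.concatenate(
        ([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf])
    )
    best_t, best_acc = -np.inf, -1.0
    for t in candidates:
        acc = float(np.mean((s > t).astype(int) == y))
        if acc > best_acc + 1e-15:
            best_t, best_acc = float(t), acc
    return best_t, best_acc


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-test p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise DomainError("pearson_r requires two equal-length samples, n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DomainError("pearson_r requires non-zero variance in both samples")
    res = sps.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def moods_median_test(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float]:
    """Mood's median test: (chi-square statistic, p-value) on 1 df.

    Pooled grand median; per group, counts of values strictly above versus
    at-or-below the median; chi-square without continuity correction.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise DomainError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    if np.ptp(pooled) == 0:
        raise DomainError("pooled data are all identical")
    grand_median = float(np.median(pooled))
    table = np.array(
        [
            [np.sum(g1 > grand_median), np.sum(g2 > grand_median)],
            [np.sum(g1 <= grand_median), np.sum(g2 <= grand_median)],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DomainError("degenerate 2x2 table (zero margin)")
    stat, p, _, _ = sps.median_test(g1, g2, ties="below", correction=False)
    return float(stat), float(p)
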