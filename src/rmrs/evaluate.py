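"""Evaluation of a continuous risk score against the count-based diagnosis.

Covers the standard surface used to benchmark continuous metabolic-
syndrome scores: the per-count distribution of the score, its Pearson
correlation (and adjusted R-squared) with the risk-factor count,
rank-based AUC against the dichotomous diagnosis, confusion-matrix
ratios at a given cutoff, the Youden-optimal cutoff, and per-subgroup
reports. Positivity convention throughout: a subject is score-positive
iff score >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "per_count_summary",
    "pearson_r",
    "auc",
    "classification_metrics",
    "youden_threshold",
    "subgroup_report",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs
    (zero variance, single-class labels)."""


@dataclass(frozen=True)
class MetricsReport:
    group: str
    n: int
    pearson_r_count_score: float | None
    adjusted_r_square: float | None
    auc: float | None
    accuracy: float | None
    recall: float | None
    specificity: float | None
    threshold_used: float
    undefined: bool = False


def per_count_summary(scores: Sequence[float], counts: Sequence[int]) -> pd.DataFrame:
    """Score distribution grouped by risk-factor count (0..5).

    Returns one row per k with n, percent of cohort, mean, sd, min, max;
    empty groups appear with n = 0 and NaN statistics.
    """
    scores = np.asarray(scores, dtype=float)
    counts = np.asarray(counts, dtype=int)
    if scores.shape != counts.shape:
        raise ValueError("scores and counts must have equal length")
    if len(scores) and (counts.min() < 0 or counts.max() > 5):
        raise ValueError("counts must be in 0..5")
    total = len(scores)
    rows = []
    for k in range(6):
        sel = scores[counts == k]
        rows.append(
            {
                "risk_factors": k,
                "n": len(sel),
                "percent": 100.0 * len(sel) / total if total else 0.0,
                "mean": sel.mean() if len(sel) else np.nan,
                "sd": sel.std(ddof=1) if len(sel) > 1 else np.nan,
                "min": sel.min() if len(sel) else np.nan,
                "max": sel.max() if len(sel) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation of x and y plus the adjusted
    R-squared of the simple linear fit y ~ x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    r = float(sps.pearsonr(x, y).statistic)
    n = len(x)
    r2 = r * r
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return r, adj_r2


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def classification_metrics(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float,
) -> tuple[float, float, float]:
    """(accuracy, recall, specificity) predicting positive iff
    score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("metrics undefined with a single class")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    accuracy = (tp + tn) / len(labels)
    recall = tp / int(pos.sum())
    specificity = tn / int((~pos).sum())
    return accuracy, recall, specificity


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = recall + specificity - 1.

    Candidates are midpoints of adjacent distinct sorted scores plus
    sentinels below the minimum and above the maximum; ties in J break
    toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("Youden threshold undefined with a single class")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else np.array([])
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    n_pos = int((labels == 1).sum())
    n_neg = len(labels) - n_pos
    best_t, best_j = candidates[0], -np.inf
    for t in candidates:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j + 1e-15:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


def subgroup_report(
    frame: pd.DataFrame,
    group_by: Sequence[str],
    score_col: str = "rmrs",
    count_col: str = "risk_factor_count",
    threshold: float = 0.547,
    min_n: int = 10,
) -> list[MetricsReport]:
    """One MetricsReport per non-empty subgroup of a scored cohort table.

    Groups containing a single diagnostic class (or below ``min_n``) get
    a report flagged ``undefined`` with None metrics rather than a crash.
    """
    for col in (*group_by, score_col, count_col):
        if col not in frame.columns:
            raise ValueError(f"column {col!r} not in frame")
    reports: list[MetricsReport] = []
    grouped = [("all", frame)] if not group_by else [
        (
            "/".join(str(v) for v in (key if isinstance(key, tuple) else (key,))),
            sub,
        )
        for key, sub in frame.groupby(list(group_by), observed=True, sort=True)
    ]
    for label, sub in grouped:
        scores = sub[score_col].to_numpy(dtype=float)
        counts = sub[count_col].to_numpy(dtype=int)
        labels = (counts >= 3).astype(int)
        if len(sub) < max(min_n, 3) or len(np.unique(labels)) < 2 or np.ptp(counts) == 0:
            reports.append(
                MetricsReport(
                    group=label, n=len(sub),
                    pearson_r_count_score=None, adjusted_r_square=None,
                    auc=None, accuracy=None, recall=None, specificity=None,
                    threshold_used=threshold, undefined=True,
                )
            )
            continue
        r, adj = pearson_r(counts, scores)
        a = auc(scores, labels)
        acc, rec, spec = classification_metrics(scores, labels, threshold)
        reports.append(
            MetricsReport(
                group=label, n=len(sub),
                pearson_r_count_score=r, adjusted_r_square=adj,
                auc=a, accuracy=acc, recall=rec, specificity=spec,
                threshold_used=threshold,
            )
        )
    return reports
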