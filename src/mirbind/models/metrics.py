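"""Binary-classification metric suite.

AUC is the Mann-Whitney rank statistic with ties averaged; threshold metrics
come from the confusion matrix at the given cut-off, with any ratio whose
denominator is zero reported as 0 (MCC likewise when a denominator factor
vanishes).  Single-class truth yields NaN AUC; the rest are still computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    bacc: float
    f1: float
    mcc: float
    precision: float
    recall: float
    specificity: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC with tie correction; NaN if one class is absent."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def compute_metrics(
    y_true, scores, threshold: float = 0.5
) -> MetricsReport:
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return metrics_from_confusion(
        tp, fp, tn, fn, auc=auc_score(y, s), threshold=threshold
    )


def metrics_from_confusion(
    tp: int, fp: int, tn: int, fn: int,
    auc: float = math.nan, threshold: float = 0.5,
) -> MetricsReport:
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(
        auc=auc,
        bacc=(recall + specificity) / 2,
        f1=f1,
        mcc=mcc,
        precision=precision,
        recall=recall,
        specificity=specificity,
        threshold=threshold,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )
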