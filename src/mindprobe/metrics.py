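"""Binary classification metrics in their closed forms."""

from __future__ import annotations

import math

import numpy as np


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) with class 1 as positive."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); defined as 0
    when any marginal factor is zero.
    """
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def balanced_accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """(sensitivity + specificity) / 2; errors if a true class is absent."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("balanced accuracy undefined when a class is absent")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative,
    counting ties as 1/2 (the normalized rank-sum statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined when a class is absent")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
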