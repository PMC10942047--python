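"""Classification metrics at a fixed threshold plus rank-statistic AUC."""

from __future__ import annotations

import warnings
from typing import Dict, Sequence

import numpy as np
from scipy.stats import rankdata


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC via the Mann-Whitney rank statistic with midrank tie correction."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # midranks
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(scores: Sequence[float], labels: Sequence[int],
                    threshold: float = 0.5) -> Dict[str, float]:
    """AUC, F1, precision, recall, specificity and accuracy at the threshold.

    Precision with no predicted positives is defined as 0 (with a warning),
    matching the zero-division convention for screening tables.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "AUC": auc_rank(s, y),
        "F1": f1,
        "Prec.": precision,
        "Rec.": recall,
        "Spec.": specificity,
        "Acc.": (tp + tn) / len(y),
    }
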