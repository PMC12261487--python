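"""The eight classification metrics, implemented from first principles.

AUC-ROC comes from the rank statistic (Mann–Whitney with midranks for
ties), AUC-PR is average precision over descending score thresholds, and
the thresholded metrics derive from the 2×2 confusion table. Everything is
written out explicitly so that library implementations can serve as an
independent cross-check rather than as the implementation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

METRIC_NAMES = ("auc_roc", "auc_pr", "acc", "bacc", "f1", "precision", "recall", "kappa")


@dataclass
class MetricReport:
    auc_roc: float | None
    auc_pr: float | None
    acc: float
    bacc: float
    f1: float
    precision: float
    recall: float
    kappa: float

    def as_dict(self) -> dict[str, float | None]:
        return asdict(self)


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC via the rank-sum identity; ties get midranks."""
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC-ROC needs both classes")
    ranks = rankdata(probs)  # average ranks on ties
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def average_precision(probs: np.ndarray, labels: np.ndarray) -> float:
    """AUC-PR as average precision, AP = Σ (R_i − R_{i−1}) · P_i over
    descending unique thresholds (tied scores form one threshold)."""
    labels = np.asarray(labels, dtype=np.float64)
    n_pos = labels.sum()
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("AUC-PR needs both classes")
    order = np.argsort(-np.asarray(probs), kind="stable")
    sorted_scores = np.asarray(probs)[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1.0 - sorted_labels)
    # keep the last index of every tied-score block
    last_of_block = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp, fp = tp[last_of_block], fp[last_of_block]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(((recall - prev_recall) * precision).sum())


def confusion(probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
              ) -> tuple[int, int, int, int]:
    pred = np.asarray(probs) >= threshold
    labels = np.asarray(labels).astype(bool)
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return tn, fp, fn, tp


def metrics_from_confusion(tn: int, fp: int, fn: int, tp: int) -> dict[str, float]:
    n = tn + fp + fn + tp
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    bacc = (sens + spec) / 2
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = sens
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    p_o = acc
    p_e = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    kappa = (p_o - p_e) / (1 - p_e) if p_e != 1.0 else 0.0
    return {"acc": acc, "bacc": bacc, "f1": f1, "precision": precision,
            "recall": recall, "kappa": kappa}


def compute_metrics(probs: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> MetricReport:
    """All eight metrics for one evaluation.

    With single-class labels the area metrics are undefined and reported
    as ``None`` with a warning; the thresholded metrics are still computed.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    try:
        auc = roc_auc(probs, labels)
        ap = average_precision(probs, labels)
    except ValueError:
        warnings.warn("single-class labels: AUC-ROC/AUC-PR undefined", RuntimeWarning,
                      stacklevel=2)
        auc = ap = None
    rest = metrics_from_confusion(*confusion(probs, labels, threshold))
    return MetricReport(auc_roc=auc, auc_pr=ap, **rest)
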