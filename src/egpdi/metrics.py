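"""Evaluation metrics for heavily imbalanced residue-level classification.

Binding residues are rare (positive:negative ratios near 0.1 or below), so
alongside the thresholded confusion-matrix metrics the threshold-free AUC
(rank statistic) and AUPR (step-integrated precision-recall) are reported.
Ratios with a zero denominator are reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricReport", "DatasetSummary", "confusion_counts",
           "compute_metrics", "auc_score", "aupr_score", "mcc_score",
           "select_threshold", "summarize_dataset"]


@dataclass
class MetricReport:
    specificity: float
    recall: float
    precision: float
    f1: float
    mcc: float
    auc: float
    aupr: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class DatasetSummary:
    n_proteins: int
    n_binding: int
    n_nonbinding: int
    pn_ratio: float


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return labels.astype(np.int64)


def confusion_counts(probabilities: np.ndarray, labels: np.ndarray,
                     threshold: float) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with the positive call being probability >= threshold."""
    labels = _check_labels(labels)
    pred = np.asarray(probabilities) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, tn, fp, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def mcc_score(tp: int, tn: int, fp: int, fn: int) -> float:
    den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return _safe_div(tp * tn - fp * fn, den)


def auc_score(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney rank statistic (tie-corrected)."""
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return 0.0
    ranks = rankdata(probabilities)
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def aupr_score(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration over all
    score thresholds (equivalently, average precision)."""
    labels = _check_labels(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        return 0.0
    order = np.argsort(-np.asarray(probabilities), kind="stable")
    y = labels[order]
    p = np.asarray(probabilities)[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # last index of each distinct threshold
    last = np.nonzero(np.diff(p, append=np.nan))[0]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    d_recall = np.diff(recall, prepend=0.0)
    return float(np.sum(precision * d_recall))


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> MetricReport:
    """Confusion-matrix metrics at `threshold` plus threshold-free AUC/AUPR.

    Spe = TN/(TN+FP), Rec = TP/(TP+FN), Pre = TP/(TP+FP),
    F1 = 2*Pre*Rec/(Pre+Rec),
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    probabilities = np.asarray(probabilities, dtype=np.float64).ravel()
    labels = _check_labels(np.asarray(labels).ravel())
    if probabilities.size != labels.size:
        raise ValueError("probabilities and labels must have equal length")
    tp, tn, fp, fn = confusion_counts(probabilities, labels, threshold)
    spe = _safe_div(tn, tn + fp)
    rec = _safe_div(tp, tp + fn)
    pre = _safe_div(tp, tp + fp)
    f1 = _safe_div(2 * pre * rec, pre + rec)
    return MetricReport(
        specificity=spe, recall=rec, precision=pre, f1=f1,
        mcc=mcc_score(tp, tn, fp, fn),
        auc=auc_score(probabilities, labels),
        aupr=aupr_score(probabilities, labels),
        threshold=threshold,
    )


def select_threshold(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """The score threshold maximizing MCC; ties go to the smallest threshold.

    Candidate thresholds are the distinct scores themselves (a call is
    probability >= threshold, so every achievable confusion matrix is
    covered).
    """
    probabilities = np.asarray(probabilities, dtype=np.float64).ravel()
    labels = _check_labels(np.asarray(labels).ravel())
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to select a threshold")
    best_t, best_mcc = None, -np.inf
    for t in np.unique(probabilities):
        mcc = mcc_score(*confusion_counts(probabilities, labels, t))
        if mcc > best_mcc + 1e-12:
            best_t, best_mcc = float(t), mcc
    return best_t


def summarize_dataset(labels_per_protein: list[np.ndarray]) -> DatasetSummary:
    """Aggregate binding/nonbinding counts; PN ratio rounded to 3 decimals."""
    n_binding = n_nonbinding = 0
    for y in labels_per_protein:
        y = _check_labels(np.asarray(y).ravel())
        n_binding += int(y.sum())
        n_nonbinding += int((y == 0).sum())
    if n_nonbinding == 0:
        raise ValueError("dataset has no nonbinding residues")
    return DatasetSummary(
        n_proteins=len(labels_per_protein),
        n_binding=n_binding,
        n_nonbinding=n_nonbinding,
        pn_ratio=round(n_binding / n_nonbinding, 3),
    )
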