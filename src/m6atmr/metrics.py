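"""Binary-classification metrics and threshold-sweep curves.

The report columns follow the field's cross-validation tables: MCC, Acc,
Sn (sensitivity/recall), Sp (specificity), Prec, F1, AUC, AUPR.  The
standard definitions are used (Prec = TP/(TP+FP), F1 = 2PS/(P+S));
``literal=True`` reproduces a commonly printed defective variant
(Prec = TP/(TP+FN), F1 without the factor 2) for auditing published tables.
Zero-denominator cases return 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

__all__ = ["ConfusionCounts", "compute_metrics", "curves",
            "confusion_from_predictions", "METRIC_COLUMNS"]

METRIC_COLUMNS = ["MCC", "Acc", "Sn", "Sp", "Prec", "F1", "AUC", "AUPR"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be nonnegative")
        if self.TP + self.FP + self.TN + self.FN == 0:
            raise ValueError("confusion table is empty")


def _safe(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def compute_metrics(counts: ConfusionCounts, literal: bool = False) -> dict[str, float]:
    """Threshold metrics {Acc, F1, Prec, Sn, Sp, MCC} from a confusion table."""
    tp, fp, tn, fn = (float(counts.TP), float(counts.FP),
                      float(counts.TN), float(counts.FN))
    acc = (tp + tn) / (tp + tn + fp + fn)
    sn = _safe(tp, tp + fn)
    sp = _safe(tn, tn + fp)
    prec = _safe(tp, tp + fn) if literal else _safe(tp, tp + fp)
    if literal:
        f1 = _safe(prec * sn, prec + sn)
    else:
        f1 = _safe(2.0 * prec * sn, prec + sn)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe(tp * tn - fp * fn, mcc_den)
    return {"Acc": acc, "F1": f1, "Prec": prec, "Sn": sn, "Sp": sp, "MCC": mcc}


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def curves(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC and PR threshold-sweep curves plus their areas.

    AUC is the trapezoidal area under the ROC curve; AUPR is the
    step-interpolated area under the PR curve (average precision).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("curves need both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    return {
        "roc": np.column_stack([fpr, tpr]),
        "pr": np.column_stack([rec, prec]),
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
    }
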