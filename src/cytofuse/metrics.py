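"""Evaluation metrics for multiclass leukocyte classification.

Besides the standard suite (confusion matrix; per-class and macro
precision/recall/F1; accuracy; Matthews correlation; macro one-vs-rest
ROC AUC) two supplementary indicators are computed:

* **EAR** (error alignment ratio): the misclassified fraction, i.e.
  1 - accuracy;
* **FIS**: the mean absolute difference of integer-encoded true and
  predicted labels.  On binary problems FIS equals EAR; for more than two
  classes its value depends on the (lexicographic) label encoding order
  and it is reported with that caveat — 0 is perfect consistency.

Zero-denominator rates are 0 by convention; multiclass MCC uses the
confusion-matrix covariance generalization, which reduces to the familiar
binary formula on 2 x 2 inputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .select_fuse import encode_labels

__all__ = [
    "confusion_matrix",
    "classification_metrics",
    "mcc",
    "ear",
    "fis",
    "roc_auc",
    "EvaluationReport",
    "evaluate",
]


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], class_map: dict[str, int]
) -> np.ndarray:
    """C x C count matrix; entry (r, c) = true class r predicted as c."""
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    c = len(class_map)
    m = np.zeros((c, c), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in class_map or p not in class_map:
            raise ValueError(f"unknown label in ({t!r}, {p!r})")
        m[class_map[t], class_map[p]] += 1
    return m


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return np.where(den > 0, num / np.where(den == 0, 1, den), 0.0)


def classification_metrics(confusion: np.ndarray) -> dict:
    """Accuracy plus per-class / macro precision, recall and F1.

    Per-class values use one-vs-rest TP/FP/FN from the confusion matrix;
    any zero denominator yields 0.
    """
    m = np.asarray(confusion, dtype=np.float64)
    if m.size == 0 or m.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return {
        "accuracy": float(tp.sum() / m.sum()),
        "precision_per_class": precision,
        "recall_per_class": recall,
        "f1_per_class": f1,
        "precision_macro": float(precision.mean()),
        "recall_macro": float(recall.mean()),
        "f1_macro": float(f1.mean()),
    }


def mcc(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient from a confusion matrix.

    Covariance form: (N*trace - t.p) / sqrt((N^2 - p.p)(N^2 - t.t)) with t
    and p the true/predicted class-count vectors; identical to the binary
    TP/TN/FP/FN formula at C = 2.  Zero denominator -> 0.
    """
    m = np.asarray(confusion, dtype=np.float64)
    n = m.sum()
    t = m.sum(axis=1)
    p = m.sum(axis=0)
    num = n * np.trace(m) - t @ p
    den = np.sqrt((n**2 - p @ p) * (n**2 - t @ t))
    return float(num / den) if den > 0 else 0.0


def ear(y_true: Sequence, y_pred: Sequence) -> float:
    """Misclassified fraction (1 - accuracy)."""
    if len(y_true) == 0:
        raise ValueError("empty prediction set")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    return float(np.mean([t != p for t, p in zip(y_true, y_pred)]))


def fis(y_true_encoded: Sequence[int], y_pred_encoded: Sequence[int]) -> float:
    """Mean absolute difference of integer-encoded labels (0 = perfect)."""
    yt = np.asarray(y_true_encoded, dtype=np.float64)
    yp = np.asarray(y_pred_encoded, dtype=np.float64)
    if yt.shape != yp.shape:
        raise ValueError("length mismatch")
    n_classes = np.unique(np.concatenate([yt, yp])).size
    if n_classes > 2:
        warnings.warn(
            "FIS depends on the label encoding order for more than 2 classes",
            stacklevel=2,
        )
    return float(np.abs(yt - yp).mean())


def roc_auc(
    y_true: Sequence[str], probabilities: np.ndarray, class_map: dict[str, int]
) -> float:
    """Macro one-vs-rest AUC by trapezoidal integration of the ROC curve.

    Classes absent from ``y_true`` are skipped with a warning.
    """
    from sklearn.metrics import roc_curve

    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[1] != len(class_map):
        raise ValueError("probability matrix shape mismatch")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    enc = np.array([class_map[t] for t in y_true])
    aucs = []
    for cls, idx in sorted(class_map.items(), key=lambda kv: kv[1]):
        pos = enc == idx
        if pos.all() or not pos.any():
            warnings.warn(f"class {cls!r} absent from one side; skipped in AUC")
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), probs[:, idx])
        aucs.append(float(np.trapezoid(tpr, fpr)))
    if not aucs:
        raise ValueError("AUC undefined: no class present on both sides")
    return float(np.mean(aucs))


@dataclasses.dataclass
class EvaluationReport:
    """Full evaluation of one prediction set."""

    confusion: np.ndarray
    class_map: dict[str, int]
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: dict[str, dict[str, float]]
    mcc: float
    auc_macro_ovr: float | None
    ear: float
    fis: float
    n_total: int
    n_error: int

    def to_dict(self) -> dict:
        return {
            "classes": sorted(self.class_map, key=self.class_map.get),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "per_class": self.per_class,
            "mcc": self.mcc,
            "auc_macro_ovr": self.auc_macro_ovr,
            "ear": self.ear,
            "fis": self.fis,
            "n_total": self.n_total,
            "n_error": self.n_error,
        }


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    probabilities: np.ndarray | None = None,
    class_map: dict[str, int] | None = None,
) -> EvaluationReport:
    """Compute the full report for one prediction set."""
    if class_map is None:
        _, class_map = encode_labels(list(y_true) + list(y_pred))
    conf = confusion_matrix(y_true, y_pred, class_map)
    base = classification_metrics(conf)
    enc_t = [class_map[t] for t in y_true]
    enc_p = [class_map[p] for p in y_pred]
    classes = sorted(class_map, key=class_map.get)
    per_class = {
        cls: {
            "precision": float(base["precision_per_class"][i]),
            "recall": float(base["recall_per_class"][i]),
            "f1": float(base["f1_per_class"][i]),
        }
        for i, cls in enumerate(classes)
    }
    auc = None
    if probabilities is not None:
        auc = roc_auc(y_true, probabilities, class_map)
    n_total = len(y_true)
    err = ear(y_true, y_pred)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fis_val = fis(enc_t, enc_p)
    return EvaluationReport(
        confusion=conf,
        class_map=class_map,
        accuracy=base["accuracy"],
        precision_macro=base["precision_macro"],
        recall_macro=base["recall_macro"],
        f1_macro=base["f1_macro"],
        per_class=per_class,
        mcc=mcc(conf),
        auc_macro_ovr=auc,
        ear=err,
        fis=fis_val,
        n_total=n_total,
        n_error=int(round(err * n_total)),
    )
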