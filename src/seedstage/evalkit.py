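"""Evaluation: confusion matrices and one-vs-rest classification metrics.

All reported numbers derive from the 4x4 confusion matrix (rows = true
stage, columns = predicted stage, class order Soil, FA, OC, FL).  For each
class, one-vs-rest counts TP/FP/FN/TN give

* sensitivity (recall) = TP / (TP + FN)
* specificity          = TN / (TN + FP)
* precision            = TP / (TP + FP)
* false-positive rate  = FP / (FP + TN)
* accuracy             = (TP + TN) / total,  error = 1 - accuracy
* F1 = 2 * precision * recall / (precision + recall)
     = 2 * TP / (2 * TP + FP + FN)

with the convention that a 0/0 ratio is reported as 0.  Summary rows give
the mean +/- sd across the four classes (sd across per-pot sequences is
available behind ``per_sequence``-style aggregation in the pipeline).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .stages import N_STAGES, STAGE_NAMES

__all__ = ["confusion_matrix", "per_class_f1", "summary_metrics",
           "MetricsReport"]

_METRIC_NAMES = ("accuracy", "error", "sensitivity", "specificity",
                 "precision", "false_positive_rate", "f1")


def confusion_matrix(truth, pred, n_classes: int = N_STAGES) -> np.ndarray:
    """Counts[i, j] = number of frames with true class i predicted as j."""
    t = np.asarray(truth, dtype=np.int64).ravel()
    p = np.asarray(pred, dtype=np.int64).ravel()
    if t.shape != p.shape:
        raise ValueError(
            f"length mismatch: {t.shape[0]} truth vs {p.shape[0]} predicted")
    return _sk_confusion(t, p, labels=np.arange(n_classes))


def _ovr_counts(cm: np.ndarray):
    cm = np.asarray(cm, dtype=np.int64)
    total = cm.sum()
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    return tp, fp, fn, tn, total


def _safe_div(num, den):
    num, den = np.asarray(num, dtype=np.float64), np.asarray(den, dtype=np.float64)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def per_class_f1(cm: np.ndarray) -> np.ndarray:
    """One-vs-rest F1 per class, 2*TP / (2*TP + FP + FN); 0 when the
    denominator vanishes."""
    tp, fp, fn, _, _ = _ovr_counts(cm)
    return _safe_div(2.0 * tp, 2.0 * tp + fp + fn)


@dataclasses.dataclass
class MetricsReport:
    """Per-class metrics plus mean +/- sd across classes."""

    confusion: np.ndarray
    per_class: dict[str, np.ndarray]     # metric name -> (n_classes,)
    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "class_order": list(STAGE_NAMES[:len(self.confusion)]),
            "confusion_matrix": self.confusion.tolist(),
            "per_class": {k: [round(float(v), 6) for v in arr]
                          for k, arr in self.per_class.items()},
            "mean": {k: round(float(v), 6) for k, v in self.mean.items()},
            "sd": {k: round(float(v), 6) for k, v in self.sd.items()},
        }

    def to_json(self, path=None, **kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def summary(self) -> str:
        names = STAGE_NAMES[:len(self.confusion)]
        lines = ["{:<22}".format("metric")
                 + "".join(f"{n:>8}" for n in names) + f"{'mean±sd':>16}"]
        for m in _METRIC_NAMES:
            row = "".join(f"{v:8.3f}" for v in self.per_class[m])
            lines.append(f"{m:<22}{row}   {self.mean[m]:.3f}±{self.sd[m]:.3f}")
        return "\n".join(lines)


def summary_metrics(cm: np.ndarray) -> MetricsReport:
    """All one-vs-rest metrics for a confusion matrix."""
    cm = np.asarray(cm, dtype=np.int64)
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn, total = _ovr_counts(cm)
    acc = _safe_div(tp + tn, total)
    per = {
        "accuracy": acc,
        "error": 1.0 - acc,
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "precision": _safe_div(tp, tp + fp),
        "false_positive_rate": _safe_div(fp, fp + tn),
        "f1": per_class_f1(cm),
    }
    mean = {k: float(v.mean()) for k, v in per.items()}
    sd = {k: float(v.std(ddof=0)) for k, v in per.items()}
    return MetricsReport(confusion=cm, per_class=per, mean=mean, sd=sd)
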