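"""Scoring: per-class accuracy, confusion matrices, confidence-retention
curves, and Welch's t-test for comparing replicate model accuracies.

Accuracies are reported in percent.  Confusion matrices are 3x3 count
matrices with rows = true class, columns = predicted class, so row sums
equal the per-class sample counts and ``per_class_accuracy[k] =
100 * confusion[k, k] / n_per_class[k]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import Prediction

log = logging.getLogger("dropclass.evaluate")

N_CLASSES = 3


@dataclass
class EvaluationReport:
    per_class_accuracy: np.ndarray  # percent, length 3
    overall_accuracy: float  # percent
    confusion: np.ndarray  # 3x3 counts, rows = true
    n_per_class: np.ndarray
    retention_curve: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class_accuracy": [round(a, 1) for a in self.per_class_accuracy.tolist()],
            "overall_accuracy": round(self.overall_accuracy, 1),
            "confusion": self.confusion.tolist(),
            "n_per_class": self.n_per_class.tolist(),
            "retention_curve": [
                {"threshold": t, "retained_fraction": f, "accuracy": a}
                for (t, f, a) in self.retention_curve
            ],
        }


def _labels_of(preds) -> np.ndarray:
    return np.array([p.label if isinstance(p, Prediction) else int(p) for p in preds])


def confusion_matrix(pred_labels, true_labels) -> np.ndarray:
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("predictions and truth must be aligned 1:1")
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(conf, (true, pred), 1)
    return conf


def score(preds, truth) -> EvaluationReport:
    """Score predictions (labels or Prediction objects) against true labels."""
    pred = _labels_of(preds)
    true = np.asarray(truth, dtype=int)
    if len(pred) != len(true):
        raise ValueError(f"got {len(pred)} predictions for {len(true)} truth labels")
    conf = confusion_matrix(pred, true)
    n_per_class = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(n_per_class > 0, 100.0 * np.diag(conf) / n_per_class, np.nan)
    overall = 100.0 * np.trace(conf) / conf.sum()
    return EvaluationReport(
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        confusion=conf,
        n_per_class=n_per_class,
    )


def retention_accuracy(preds, truth, thresholds) -> list:
    """For each confidence threshold: (threshold, retained fraction,
    accuracy in percent on the retained subset).

    Predictions must be Prediction objects (they carry confidences).  An
    empty retained subset has undefined accuracy, reported as None and
    flagged with a warning, never imputed as 0.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    true = np.asarray(truth, dtype=int)
    conf = np.array([p.confidence for p in preds])
    pred = _labels_of(preds)
    curve = []
    for t in thresholds:
        keep = conf >= t
        frac = float(keep.mean()) if len(keep) else 0.0
        if keep.sum() == 0:
            log.warning("retention threshold %s retains no predictions; accuracy undefined", t)
            curve.append((t, frac, None))
        else:
            acc = 100.0 * float((pred[keep] == true[keep]).mean())
            curve.append((t, frac, acc))
    return curve


def welch_t_test(scores_a, scores_b):
    """Welch's two-sample t-test (unequal variances), two-sided.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of
    freedom.  Two identical constant samples are a degenerate case defined
    as (t=0, df=n_a+n_b-2, p=1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs length >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both variances are zero with unequal means; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t_test(scores_a, scores_b):
    """Paired t-test (index-paired), two-sided; returns (t, df, p)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired samples must be same length >= 2")
    if np.var(a - b, ddof=1) == 0 and np.all(a == b):
        return 0.0, float(len(a) - 1), 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(len(a) - 1), float(res.pvalue)
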