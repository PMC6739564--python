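"""Evaluation metrics for multilabel and per-label binary predictions.

Multilabel metrics over true label sets L_k and predicted sets L_k*:

* aiming          mean |L_k ∩ L_k*| / |L_k*|   (precision of predictions;
                  a pseudo-divisor 1 replaces |L_k*| = 0, making the term 0)
* coverage        mean |L_k ∩ L_k*| / |L_k|    (recall of the true sets)
* accuracy        mean |L_k ∩ L_k*| / |L_k ∪ L_k*|  (Jaccard)
* absolute true   fraction of exact set matches — the most stringent metric
* hamming loss    mean |L_k ⊖ L_k*| / M        (per-label disagreement rate)

Per-label binary metrics are the usual confusion-matrix ratios plus a
trapezoidal ROC AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


@dataclass
class MultiLabelMetricReport:
    aiming: float
    coverage: float
    accuracy: float
    absolute_true: float
    hamming_loss: float
    n_samples: int
    n_labels: int

    METRIC_FIELDS = ("aiming", "coverage", "accuracy", "absolute_true", "hamming_loss")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_frame(self) -> pd.DataFrame:
        """One-row table for tabulation across runs."""
        return pd.DataFrame([asdict(self)])


@dataclass
class BinaryMetricReport:
    accuracy: float
    specificity: float
    recall: float
    f1: float
    tp: int
    tn: int
    fp: int
    fn: int
    auc: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as 0",
                      stacklevel=3)
        return 0.0
    return num / den


def multilabel_metrics(
    true_sets,
    pred_sets,
    n_labels: int,
    allow_empty_true: bool = False,
) -> MultiLabelMetricReport:
    """Compute the five multilabel metrics over paired label sets.

    ``true_sets`` and ``pred_sets`` are equal-length sequences of sets of
    labels from an ``n_labels``-sized universe.  Empty true sets violate
    the at-least-one-label dataset invariant and raise unless
    ``allow_empty_true`` is set (their coverage term is then 0).
    """
    if len(true_sets) != len(pred_sets):
        raise ValueError("true_sets and pred_sets must have equal length")
    if len(true_sets) == 0:
        raise ValueError("no samples to evaluate")
    aiming = coverage = accuracy = absolute = hamming = 0.0
    for k, (t, p) in enumerate(zip(true_sets, pred_sets)):
        t, p = frozenset(t), frozenset(p)
        if not t and not allow_empty_true:
            raise ValueError(f"sample {k} has an empty true label set")
        inter = len(t & p)
        aiming += inter / (len(p) if p else 1)  # pseudo-divisor 1
        coverage += inter / len(t) if t else 0.0
        union = len(t | p)
        accuracy += inter / union if union else 1.0
        absolute += 1.0 if t == p else 0.0
        hamming += len(t ^ p) / n_labels
    n = len(true_sets)
    return MultiLabelMetricReport(
        aiming=aiming / n,
        coverage=coverage / n,
        accuracy=accuracy / n,
        absolute_true=absolute / n,
        hamming_loss=hamming / n,
        n_samples=n,
        n_labels=n_labels,
    )


def binary_metrics(tp: int, tn: int, fp: int, fn: int) -> BinaryMetricReport:
    """Confusion-matrix metrics; zero-denominator ratios report 0 with a
    warning."""
    for name, v in (("tp", tp), ("tn", tn), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    total = tp + tn + fp + fn
    if total < 1:
        raise ValueError("empty confusion matrix")
    return BinaryMetricReport(
        accuracy=(tp + tn) / total,
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
        recall=_safe_ratio(tp, tp + fn, "recall"),
        f1=_safe_ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        tp=tp, tn=tn, fp=fp, fn=fn,
    )


def auc_trapezoidal(scores, truth) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Equal scores are grouped into a single threshold step, so the result
    coincides with the tie-corrected Mann-Whitney statistic U/(n1*n0).
    Requires both classes present in ``truth``.
    """
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("scores and truth must have equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("truth must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present in truth")
    return float(roc_auc_score(y, s))
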