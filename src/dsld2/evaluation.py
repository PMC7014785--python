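"""Confusion metrics, FDR control, and ROC / precision-recall evaluation.

Calls are scored against simulation truth.  Two call sets are tabulated per
method: DE1 (raw p < alpha) and DE2 (Benjamini-Hochberg adjusted p < fdr),
with empirical false discovery rates FDR1 and FDR2 = FP / (FP + TP) among
the respective calls.  Threshold metrics (precision, accuracy, FPR,
sensitivity, MCC) are computed from the DE1 calls; ranking metrics (ROC-AUC
and the precision-recall curve) score genes by -p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionCounts",
    "ConfusionMetrics",
    "UndefinedMetricError",
    "bh_adjust",
    "confusion",
    "roc_pr",
    "RocPrResult",
    "group_histogram",
    "metric_row",
    "metric_table",
]


class UndefinedMetricError(ValueError):
    """Raised when a curve metric is requested for single-class truth."""


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    """Derived metrics; zero-denominator entries are 0 and listed in ``undefined``."""

    counts: ConfusionCounts
    precision: float
    fdr: float
    accuracy: float
    fpr: float
    sensitivity: float
    mcc: float
    undefined: tuple = ()


def _ratio(num, den, name, undefined):
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def confusion(calls, truth) -> ConfusionMetrics:
    """Confusion counts and derived metrics of binary calls against truth."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have the same length")
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    tn = int(np.sum(~calls & ~truth))
    fn = int(np.sum(~calls & truth))
    c = ConfusionCounts(tp, fp, tn, fn)
    und: list[str] = []
    precision = _ratio(tp, tp + fp, "precision", und)
    fdr = _ratio(fp, tp + fp, "fdr", und)
    accuracy = _ratio(tp + tn, c.total, "accuracy", und)
    fpr = _ratio(fp, fp + tn, "fpr", und)
    sens = _ratio(tp, tp + fn, "sensitivity", und)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        und.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return ConfusionMetrics(c, precision, fdr, accuracy, fpr, sens, mcc,
                            tuple(und))


@dataclass
class RocPrResult:
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    auc: float
    precision: np.ndarray
    recall: np.ndarray
    pr_thresholds: np.ndarray
    pr_auc: float


def roc_pr(scores, truth) -> RocPrResult:
    """ROC and precision-recall curves for continuous scores (e.g. -p or |z|).

    ROC-AUC is the trapezoidal area (ties grouped by threshold); the PR
    summary is the interpolation-free step-wise area (average precision).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise UndefinedMetricError("truth must contain both classes")
    fpr, tpr, thr = roc_curve(truth, scores)
    prec, rec, pthr = precision_recall_curve(truth, scores)
    return RocPrResult(
        fpr=fpr, tpr=tpr, roc_thresholds=thr, auc=float(auc(fpr, tpr)),
        precision=prec, recall=rec, pr_thresholds=pthr,
        pr_auc=float(average_precision_score(truth, scores)),
    )


def group_histogram(calls, group_id, n_groups: int = 5) -> np.ndarray:
    """Counts of positive calls within each DE group 0..n_groups."""
    calls = np.asarray(calls, dtype=bool)
    group_id = np.asarray(group_id, dtype=int)
    if calls.shape != group_id.shape:
        raise ValueError("calls and group_id must have the same length")
    return np.bincount(group_id[calls], minlength=n_groups + 1)


def metric_row(p, truth, alpha: float = 0.05, fdr: float = 0.05,
               p_adj=None) -> dict:
    """One evaluation row for a method's per-gene p-values against truth.

    Returns DE1/DE2 call counts, FDR1/FDR2 empirical false discovery rates,
    threshold metrics at p < alpha, and ROC / PR areas on -p.
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    q = bh_adjust(p) if p_adj is None else np.asarray(p_adj, dtype=float)
    calls1 = p < alpha
    calls2 = q < fdr
    m1 = confusion(calls1, truth)
    m2 = confusion(calls2, truth)
    curves = roc_pr(-p, truth)
    return {
        "de1": int(calls1.sum()),
        "de2": int(calls2.sum()),
        "fdr1": m1.fdr,
        "fdr2": m2.fdr,
        "precision": m1.precision,
        "accuracy": m1.accuracy,
        "fpr": m1.fpr,
        "sensitivity": m1.sensitivity,
        "mcc": m1.mcc,
        "auc": curves.auc,
        "pr_auc": curves.pr_auc,
    }


def metric_table(pvalues: dict[str, np.ndarray], truth, alpha: float = 0.05,
                 fdr: float = 0.05, **annotations) -> pd.DataFrame:
    """Evaluation table over methods: one :func:`metric_row` per method."""
    rows = []
    for method, p in pvalues.items():
        row = {"method": method, **annotations,
               **metric_row(p, truth, alpha=alpha, fdr=fdr)}
        rows.append(row)
    return pd.DataFrame(rows)
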