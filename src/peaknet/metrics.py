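"""Multi-label accuracy assessment: ROC/AUC, precision-recall, operating points.

AUC is the rank statistic (probability that a random positive outscores a
random negative, midranks for ties); AUPRC is the step-wise area under
precision versus recall.  Cells whose test labels are single-class have
undefined metrics: the per-cell vectors carry NaN there and the means are
taken over defined cells only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (single-class labels)."""


def _check(labels, scores):
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D and equal length")
    return labels, scores


def auc(labels, scores) -> float:
    """Rank-statistic AUC with midrank tie handling."""
    labels, scores = _check(labels, scores)
    npos = labels.sum()
    if npos == 0 or npos == len(labels):
        raise UndefinedMetricError("AUC undefined: only one class present")
    return float(_skm.roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Step-wise area under the precision-recall curve."""
    labels, scores = _check(labels, scores)
    if labels.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined: no positives")
    return float(_skm.average_precision_score(labels, scores))


def roc_points(labels, scores):
    """(fpr, tpr, thresholds) at every distinct score threshold."""
    labels, scores = _check(labels, scores)
    return _skm.roc_curve(labels, scores, drop_intermediate=False)


def recall_at_fpr(labels, scores, max_fpr: float) -> float:
    """True-positive rate at the loosest threshold with FPR <= ``max_fpr``."""
    if labels_sum_degenerate(labels):
        raise UndefinedMetricError("recall undefined: only one class present")
    fpr, tpr, _ = roc_points(labels, scores)
    ok = fpr <= max_fpr
    return float(tpr[ok].max()) if ok.any() else 0.0


def recall_at_fdr(labels, scores, max_fdr: float) -> float:
    """Recall at the loosest threshold whose FDR (1 - precision) <= ``max_fdr``."""
    labels, scores = _check(labels, scores)
    if labels_sum_degenerate(labels):
        raise UndefinedMetricError("recall undefined: only one class present")
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    ok = precision >= 1.0 - max_fdr
    return float(recall[ok].max()) if ok.any() else 0.0


def labels_sum_degenerate(labels) -> bool:
    labels = np.asarray(labels).astype(int)
    return labels.sum() in (0, len(labels))


@dataclass
class EvalReport:
    """Per-cell and averaged accuracy of a multi-task model."""

    per_cell_auc: np.ndarray
    per_cell_auprc: np.ndarray
    mean_auc: float
    mean_auprc: float
    cell_names: list = field(default_factory=list)
    roc_curves: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        names = self.cell_names or [f"cell_{t}" for t in range(len(self.per_cell_auc))]
        return pd.DataFrame(
            {"cell": names, "auc": self.per_cell_auc, "auprc": self.per_cell_auprc}
        )


def evaluate(labels, scores, cell_names=None, keep_curves=False) -> EvalReport:
    """Score an (N, T) binary label matrix against (N, T) predictions."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have matching shape")
    T = labels.shape[1]
    aucs = np.full(T, np.nan)
    auprcs = np.full(T, np.nan)
    curves = []
    for t in range(T):
        col, s = labels[:, t], scores[:, t]
        try:
            aucs[t] = auc(col, s)
        except UndefinedMetricError:
            pass
        try:
            auprcs[t] = auprc(col, s)
        except UndefinedMetricError:
            pass
        if keep_curves and not np.isnan(aucs[t]):
            curves.append(roc_points(col, s))
        elif keep_curves:
            curves.append(None)
    return EvalReport(
        per_cell_auc=aucs,
        per_cell_auprc=auprcs,
        mean_auc=float(np.nanmean(aucs)) if np.isfinite(aucs).any() else np.nan,
        mean_auprc=float(np.nanmean(auprcs)) if np.isfinite(auprcs).any() else np.nan,
        cell_names=list(cell_names) if cell_names is not None else [],
        roc_curves=curves,
    )
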