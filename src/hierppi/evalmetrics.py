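"""Evaluation metrics: micro-F1, best-F1 threshold sweep, per-type AUPR,
perturbation confusion rates, and intersection-over-union of residue sets.

All multi-label metrics treat each interaction type as a one-vs-all binary
problem; micro averaging pools every (pair, type) decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from .tgnn import N_TYPES


@dataclass
class MetricReport:
    micro_f1_at_threshold: float
    best_f1: float
    best_threshold: float
    aupr_per_type: list
    macro_aupr: float | None
    n_test: int
    fpr: float | None = None
    fnr: float | None = None
    fdr: float | None = None

    def to_dict(self) -> dict:
        return {
            "micro_f1@0.5": self.micro_f1_at_threshold,
            "best_f1": self.best_f1,
            "best_threshold": self.best_threshold,
            **{f"aupr_type_{k}": v for k, v in enumerate(self.aupr_per_type)},
            "macro_aupr": self.macro_aupr,
            "n_test": self.n_test,
            "fpr": self.fpr, "fnr": self.fnr, "fdr": self.fdr,
        }


def _flatten(probs, targets):
    P = np.asarray(probs, dtype=np.float64).reshape(len(probs), -1)
    Y = np.asarray(targets, dtype=np.float64).reshape(len(targets), -1)
    if P.shape != Y.shape:
        raise ValueError("probs and targets shapes disagree")
    return P.ravel(), Y.ravel()


def micro_f1(probs, targets, threshold: float = 0.5) -> float:
    """Micro-averaged F1 over all (pair, type) decisions at a threshold."""
    p, y = _flatten(probs, targets)
    pred = p >= threshold
    tp = float(np.sum(pred & (y == 1)))
    fp = float(np.sum(pred & (y == 0)))
    fn = float(np.sum(~pred & (y == 1)))
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("no positives anywhere; micro-F1 defined as 0")
        return 0.0
    return 2 * tp / denom


def best_f1(probs, targets) -> tuple[float, float]:
    """Maximum micro-F1 over the grid of all distinct predicted scores.

    Ties are broken toward the lowest threshold.  Predictions use
    ``p >= threshold``.
    """
    p, y = _flatten(probs, targets)
    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(1 - y_sorted)
    total_pos = tp_cum[-1]
    # candidate thresholds: each distinct score (predict positive for >= t)
    is_last_of_value = np.r_[p_sorted[1:] != p_sorted[:-1], True]
    idx = np.nonzero(is_last_of_value)[0]
    tp, fp = tp_cum[idx], fp_cum[idx]
    fn = total_pos - tp
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    best_pos = int(np.argmax(f1))
    # ties -> lowest threshold (later in descending order)
    ties = np.nonzero(f1 == f1[best_pos])[0]
    best_pos = int(ties[-1])
    return float(f1[best_pos]), float(p_sorted[idx[best_pos]])


def aupr_per_type(probs, targets) -> list:
    """One-vs-all AUPR per type (interpolation-free step summation).

    A type with no positive targets gets ``None`` with a warning.
    """
    P = np.asarray(probs, dtype=np.float64)
    Y = np.asarray(targets, dtype=np.float64)
    out = []
    for k in range(P.shape[1]):
        if Y[:, k].sum() == 0:
            warnings.warn(f"type {k}: no positives; AUPR undefined")
            out.append(None)
        else:
            out.append(float(average_precision_score(Y[:, k], P[:, k])))
    return out


def confusion_rates(pred_binary, targets) -> tuple:
    """(FPR, FNR, FDR) over flattened decisions; empty denominators -> None."""
    pred = np.asarray(pred_binary, dtype=bool).ravel()
    y = np.asarray(targets, dtype=np.float64).ravel()
    tp = float(np.sum(pred & (y == 1)))
    fp = float(np.sum(pred & (y == 0)))
    fn = float(np.sum(~pred & (y == 1)))
    tn = float(np.sum(~pred & (y == 0)))

    def rate(num, den, name):
        if den == 0:
            warnings.warn(f"{name}: empty denominator")
            return None
        return num / den

    return (
        rate(fp, fp + tn, "FPR"),
        rate(fn, fn + tp, "FNR"),
        rate(fp, fp + tp, "FDR"),
    )


def iou(set_a, set_b) -> float:
    """Intersection over union of two residue index sets; both empty -> 0."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("IoU of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def pr_curve(probs, targets, type_index: int):
    """Two-column precision-recall curve for one type (step-wise points).

    Returns ``(recall, precision)`` arrays ordered by increasing recall,
    suitable for a two-column TSV.
    """
    from sklearn.metrics import precision_recall_curve

    P = np.asarray(probs, dtype=np.float64)
    Y = np.asarray(targets, dtype=np.float64)
    precision, recall, _ = precision_recall_curve(Y[:, type_index], P[:, type_index])
    order = np.argsort(recall, kind="stable")
    return recall[order], precision[order]


def evaluate(probs, targets, threshold: float = 0.5) -> MetricReport:
    """Full metric report for a set of pair predictions."""
    bf1, bthr = best_f1(probs, targets)
    auprs = aupr_per_type(probs, targets)
    defined = [a for a in auprs if a is not None]
    return MetricReport(
        micro_f1_at_threshold=micro_f1(probs, targets, threshold),
        best_f1=bf1,
        best_threshold=bthr,
        aupr_per_type=auprs,
        macro_aupr=float(np.mean(defined)) if defined else None,
        n_test=len(np.asarray(probs)),
    )
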