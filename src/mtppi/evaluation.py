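"""Performance measures and the independent-AUC significance test.

Dataset-level metrics are micro-averaged over unmasked residues pooled
across proteins; the per-protein error analysis is a separate view and
the two are never mixed. Degenerate inputs (a single class, zero
variance) yield ``None`` rather than a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


class DegenerateMetricError(ValueError):
    """Raised when a metric is undefined for the given class composition."""


def _observed(scores, labels, mask):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    if not (scores.shape == labels.shape == mask.shape):
        raise ValueError("scores/labels/mask shape mismatch")
    return scores[mask], labels[mask].astype(int)


def auc_roc(scores, labels, mask) -> float:
    """Area under the ROC curve over unmasked residues.

    Equals the Mann-Whitney probability P(score_pos > score_neg) plus half
    the tie probability; invariant under strictly monotone transforms of
    the scores.
    """
    s, y = _observed(scores, labels, mask)
    if len(np.unique(y)) < 2:
        raise DegenerateMetricError(
            "AUC ROC needs at least one positive and one negative"
        )
    return float(roc_auc_score(y, s))


def auc_pr(scores, labels, mask) -> float:
    """Area under the precision-recall curve (step-wise interpolation)."""
    s, y = _observed(scores, labels, mask)
    if not (y == 1).any():
        raise DegenerateMetricError("AUC PR needs at least one positive")
    return float(average_precision_score(y, s))


def confusion_counts(scores, labels, mask, threshold: float = 0.5):
    s, y = _observed(scores, labels, mask)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    return tp, fp, fn, tn


def accuracy(scores, labels, mask, threshold: float = 0.5) -> float:
    tp, fp, fn, tn = confusion_counts(scores, labels, mask, threshold)
    return (tp + tn) / (tp + fp + fn + tn)


def precision(scores, labels, mask, threshold: float = 0.5) -> Optional[float]:
    tp, fp, _, _ = confusion_counts(scores, labels, mask, threshold)
    return tp / (tp + fp) if tp + fp else None


def recall(scores, labels, mask, threshold: float = 0.5) -> Optional[float]:
    tp, _, fn, _ = confusion_counts(scores, labels, mask, threshold)
    return tp / (tp + fn) if tp + fn else None


def specificity(scores, labels, mask, threshold: float = 0.5) -> Optional[float]:
    _, fp, _, tn = confusion_counts(scores, labels, mask, threshold)
    return tn / (tn + fp) if tn + fp else None


def f1_score(scores, labels, mask, threshold: float = 0.5) -> Optional[float]:
    p = precision(scores, labels, mask, threshold)
    r = recall(scores, labels, mask, threshold)
    if p is None or r is None or p + r == 0:
        return None
    return 2 * p * r / (p + r)


def mcc(scores, labels, mask, threshold: float = 0.5) -> Optional[float]:
    tp, fp, fn, tn = confusion_counts(scores, labels, mask, threshold)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / np.sqrt(denom)


def multiclass_accuracy(probs, labels, mask) -> float:
    """Accuracy of the argmax class over unmasked residues (S3/S8)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    pred = probs.argmax(axis=-1)
    return float((pred[mask] == labels[mask].astype(int)).mean())


def pcc(pred, target, mask) -> float:
    """Pearson correlation over unmasked pairs; needs nonzero variance."""
    mask = np.asarray(mask, dtype=bool)
    p = np.asarray(pred, dtype=float)[mask]
    t = np.asarray(target, dtype=float)[mask]
    if len(p) < 2 or p.std() == 0 or t.std() == 0:
        raise DegenerateMetricError("PCC needs >= 2 pairs with variance")
    return float(np.corrcoef(p, t)[0, 1])


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an AUC (Hanley & McNeil 1982)."""
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("positive and negative counts must be > 0")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc * auc)
        + (n_neg - 1) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return float(np.sqrt(var))


def compare_auc_one_sided(
    auc1: float, n_pos1: int, n_neg1: int,
    auc2: float, n_pos2: int, n_neg2: int,
) -> float:
    """One-sided p-value for auc1 > auc2 on independent samples.

    z = (auc1 - auc2) / sqrt(SE1^2 + SE2^2) with Hanley-McNeil standard
    errors; upper-tail normal p-value. Equal AUCs give exactly 0.5.
    """
    for a in (auc1, auc2):
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"AUC {a} outside [0, 1]")
    if auc1 == auc2:
        return 0.5
    se1 = hanley_mcneil_se(auc1, n_pos1, n_neg1)
    se2 = hanley_mcneil_se(auc2, n_pos2, n_neg2)
    z = (auc1 - auc2) / np.sqrt(se1 * se1 + se2 * se2)
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# Aggregate reports

@dataclass
class MetricsReport:
    """task -> metric name -> value, plus unmasked residue counts."""

    metrics: Dict[str, Dict[str, Optional[float]]]
    counts: Dict[str, int]


def evaluate_predictions(
    predictions: Dict[str, np.ndarray],
    targets: Dict[str, np.ndarray],
    masks: Dict[str, np.ndarray],
) -> MetricsReport:
    """Micro-averaged per-task metrics over pooled unmasked residues.

    ``predictions`` holds per-residue probability arrays (binary tasks:
    positive-class score; multi-class: (N, K)) and raw SA values.
    """
    metrics: Dict[str, Dict[str, Optional[float]]] = {}
    counts: Dict[str, int] = {}
    for task, pred in predictions.items():
        m = np.asarray(masks[task], dtype=bool)
        counts[task] = int(m.sum())
        if counts[task] == 0:
            metrics[task] = {}
            continue
        y = targets[task]
        if task in ("IF", "BU"):
            try:
                roc = auc_roc(pred, y, m)
                pr = auc_pr(pred, y, m)
            except DegenerateMetricError:
                roc = pr = None
            metrics[task] = {
                "auc_roc": roc,
                "auc_pr": pr,
                "accuracy": accuracy(pred, y, m),
                "precision": precision(pred, y, m),
                "recall": recall(pred, y, m),
                "specificity": specificity(pred, y, m),
                "mcc": mcc(pred, y, m),
                "f1": f1_score(pred, y, m),
            }
        elif task in ("S3", "S8"):
            metrics[task] = {"accuracy": multiclass_accuracy(pred, y, m)}
        elif task == "SA":
            try:
                r = pcc(pred, y, m)
            except DegenerateMetricError:
                r = None
            metrics[task] = {"pcc": r}
        else:
            raise ValueError(f"unknown task {task!r}")
    return MetricsReport(metrics, counts)


@dataclass
class ProteinErrorRow:
    protein_id: str
    n_interface_residues: int
    mean_if_auc: Optional[float]  # None when AUC undefined for the protein
    related_scores: Dict[str, float]


def per_protein_analysis(
    predictions_over_repeats: Sequence[Dict[str, Dict[str, np.ndarray]]],
    records,
) -> tuple[List[ProteinErrorRow], Dict[str, Dict[str, float]]]:
    """Mean per-protein interface AUC over repeats plus OLS regressions.

    ``predictions_over_repeats[r][protein_id][task]`` holds one repeat's
    per-residue predictions. Returns one row per protein (proteins whose
    interface AUC is undefined are flagged with ``None`` and excluded
    from the regressions) and, per related task, the slope/intercept/R^2
    of the task score regressed against the mean interface AUC.
    """
    if len(predictions_over_repeats) < 2:
        raise ValueError("need >= 2 repeats of predictions")
    rows: List[ProteinErrorRow] = []
    for rec in records:
        m_if = rec.masks["IF"]
        y_if = np.asarray(rec.labels["IF"])
        n_iface = int(((y_if == 1) & m_if).sum())
        aucs = []
        for rep in predictions_over_repeats:
            pred = rep[rec.protein_id]
            try:
                aucs.append(auc_roc(pred["IF"], y_if, m_if))
            except DegenerateMetricError:
                aucs = []
                break
        mean_auc = float(np.mean(aucs)) if aucs else None
        related: Dict[str, float] = {}
        for task in ("BU", "S3", "SA"):
            vals = []
            for rep in predictions_over_repeats:
                pred = rep[rec.protein_id]
                if task not in pred:
                    continue
                m = rec.masks[task]
                if not m.any():
                    continue
                if task == "BU":
                    vals.append(accuracy(pred[task], rec.labels[task], m))
                elif task == "S3":
                    vals.append(
                        multiclass_accuracy(pred[task], rec.labels[task], m)
                    )
                else:
                    try:
                        vals.append(pcc(pred[task], rec.labels[task], m))
                    except DegenerateMetricError:
                        continue
            if vals:
                related[task] = float(np.mean(vals))
        rows.append(ProteinErrorRow(rec.protein_id, n_iface, mean_auc, related))

    regressions: Dict[str, Dict[str, float]] = {}
    for task in ("BU", "S3", "SA"):
        xs, ys = [], []
        for row in rows:
            if row.mean_if_auc is not None and task in row.related_scores:
                xs.append(row.mean_if_auc)
                ys.append(row.related_scores[task])
        if len(xs) >= 3 and np.std(xs) > 0:
            fit = stats.linregress(xs, ys)
            regressions[task] = {
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r_squared": float(fit.rvalue ** 2),
            }
    return rows, regressions
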