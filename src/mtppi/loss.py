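"""Masked multi-task cost function.

The total training cost is the weighted sum

    L = alpha*L_IF + beta*L_BU + gamma*L_S3 + delta*L_S8 + epsilon*L_SA

where each task loss is the mean cross-entropy (classification: IF, BU,
S3, S8) or mean squared error (regression: SA) over the *unmasked*
residues of the batch. Masked residues — padding, residues without a
usable label, and the whole interface vector of proteins lacking any
interface annotation — contribute exactly nothing, which is what lets the
model keep learning the structural tasks on proteins with missing
interface data. Interface positives are up-weighted by the class-imbalance
weight (the non-interface/interface residue ratio of the training and
validation sets).

Reduction convention: each task loss is the mean over all unmasked
residues pooled across the batch (class weights scale the numerator
only), so task weights stay interpretable across variable-length batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

TASKS = ("IF", "BU", "S3", "S8", "SA")
CLASSIFICATION_TASKS = ("IF", "BU", "S3", "S8")
TASK_N_CLASSES = {"IF": 2, "BU": 2, "S3": 3, "S8": 8, "SA": 1}

_EPS = 1e-12


@dataclass
class LossWeights:
    """Eq.-style task coefficients plus the interface class weight.

    Tasks absent from the active model must carry weight exactly 0; at
    least one weight must be positive.
    """

    alpha: float = 0.0  # IF
    beta: float = 0.0  # BU
    gamma: float = 0.0  # S3
    delta: float = 0.0  # S8
    epsilon: float = 0.0  # SA
    if_positive_class_weight: float = 1.0

    _FIELD_BY_TASK = {
        "IF": "alpha", "BU": "beta", "S3": "gamma", "S8": "delta",
        "SA": "epsilon",
    }

    def __post_init__(self) -> None:
        vals = [self.alpha, self.beta, self.gamma, self.delta, self.epsilon]
        if any(v < 0 for v in vals):
            raise ValueError("task weights must be non-negative")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one task weight must be positive")
        if not self.if_positive_class_weight > 0:
            raise ValueError("if_positive_class_weight must be positive")

    def __getitem__(self, task: str) -> float:
        return getattr(self, self._FIELD_BY_TASK[task])

    @property
    def active_tasks(self) -> Tuple[str, ...]:
        return tuple(t for t in TASKS if self[t] > 0)

    def as_dict(self) -> Dict[str, float]:
        return {t: self[t] for t in TASKS}


@dataclass
class TaskLossReport:
    """Per-task scalar losses, unmasked counts and the weighted total."""

    losses: Dict[str, float]
    counts: Dict[str, int]
    total: float


def _check_probabilities(p: np.ndarray) -> None:
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite prediction")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("classification predictions must lie in [0, 1]")


def task_loss(
    predictions: np.ndarray,
    targets: np.ndarray,
    mask: np.ndarray,
    task_kind: str,
    if_positive_class_weight: float = 1.0,
) -> float:
    """Masked per-task loss.

    Parameters
    ----------
    predictions:
        Classification: (L, K) per-residue probability vectors.
        Regression (``task_kind="SA"``): (L,) real predictions.
    targets:
        Classification: (L,) integer class ids. Regression: (L,) reals.
    mask:
        (L,) boolean, True = observed. With an all-false mask the loss
        is 0 by definition.
    task_kind:
        One of IF, BU, S3, S8 (cross-entropy) or SA (squared error).
        For IF, residues with target 1 are weighted by
        ``if_positive_class_weight``.
    """
    if task_kind not in TASKS:
        raise ValueError(f"unknown task {task_kind!r}")
    mask = np.asarray(mask, dtype=bool)
    predictions = np.asarray(predictions, dtype=float)
    targets = np.asarray(targets)
    if mask.shape[0] != predictions.shape[0] or mask.shape[0] != targets.shape[0]:
        raise ValueError("predictions/targets/mask length mismatch")
    n = int(mask.sum())
    if n == 0:
        return 0.0
    if task_kind == "SA":
        if not np.all(np.isfinite(predictions[mask])):
            raise ValueError("non-finite prediction")
        err = predictions[mask] - targets[mask].astype(float)
        return float(np.mean(err * err))
    _check_probabilities(predictions[mask])
    t = targets[mask].astype(int)
    p = predictions[mask, t]
    ce = -np.log(np.clip(p, _EPS, None))
    if task_kind == "IF" and if_positive_class_weight != 1.0:
        w = np.where(t == 1, if_positive_class_weight, 1.0)
        ce = ce * w
    return float(ce.sum() / n)


def total_loss(task_losses: Dict[str, float], weights: LossWeights) -> float:
    """Weighted sum of per-task losses (the total cost function).

    ``task_losses`` must cover exactly the active (positive-weight) tasks;
    supplying a loss for an inactive task is an error.
    """
    active = set(weights.active_tasks)
    extra = set(task_losses) - active
    if extra:
        raise ValueError(f"loss provided for inactive task(s): {sorted(extra)}")
    missing = active - set(task_losses)
    if missing:
        raise ValueError(f"missing loss for active task(s): {sorted(missing)}")
    return float(sum(weights[t] * task_losses[t] for t in task_losses))


def batch_loss(
    predictions: Dict[str, np.ndarray],
    targets: Dict[str, np.ndarray],
    masks: Dict[str, np.ndarray],
    weights: LossWeights,
) -> TaskLossReport:
    """Per-task and total loss over a (possibly concatenated) batch."""
    losses, counts = {}, {}
    for t in weights.active_tasks:
        losses[t] = task_loss(
            predictions[t], targets[t], masks[t], t,
            if_positive_class_weight=weights.if_positive_class_weight,
        )
        counts[t] = int(np.asarray(masks[t], dtype=bool).sum())
    return TaskLossReport(losses, counts, total_loss(losses, weights))


#: Method B groupings of similar tasks. "prose" pairs the secondary
#: structure tasks (S3, S8) and the accessibility tasks (BU, SA); the
#: alternative "equation" reading pairs (BU, S3) and (S8, SA).
METHOD_B_PAIRINGS = {
    "prose": (("S3", "S8"), ("BU", "SA")),
    "equation": (("BU", "S3"), ("S8", "SA")),
}


def weight_scheme(
    method: str,
    active_tasks: Sequence[str],
    if_positive_class_weight: float = 1.0,
    method_b_pairing: str = "prose",
) -> LossWeights:
    """Construct the Eq. coefficients for weighting methods A, B and C.

    Method A: all active tasks weighted equally. Method B: each group of
    similar tasks shares, in total, the weight of one ungrouped task
    (split equally inside the group; a singleton group keeps full
    weight). Method C: the interface loss carries 50% of the total cost,
    i.e. alpha = beta + gamma + delta + epsilon with the non-interface
    weights equal. All schemes are normalized to sum to 1.
    """
    active = tuple(dict.fromkeys(active_tasks))
    if "IF" not in active:
        raise ValueError("active_tasks must include IF")
    unknown = set(active) - set(TASKS)
    if unknown:
        raise ValueError(f"unknown task(s): {sorted(unknown)}")

    raw: Dict[str, float] = {}
    if method == "A":
        raw = {t: 1.0 for t in active}
    elif method == "B":
        try:
            groups = METHOD_B_PAIRINGS[method_b_pairing]
        except KeyError:
            raise ValueError(
                f"unknown method_b_pairing {method_b_pairing!r}"
            ) from None
        raw["IF"] = 1.0
        grouped = {t for g in groups for t in g}
        for t in active:
            if t != "IF" and t not in grouped:
                raw[t] = 1.0
        for g in groups:
            present = [t for t in g if t in active]
            for t in present:
                raw[t] = 1.0 / len(present)
    elif method == "C":
        others = [t for t in active if t != "IF"]
        if not others:
            raise ValueError("method C needs at least one related task")
        raw["IF"] = 1.0
        for t in others:
            raw[t] = 1.0 / len(others)
    else:
        raise ValueError(f"unknown weighting method {method!r}")

    s = sum(raw.values())
    fields = {LossWeights._FIELD_BY_TASK[t]: w / s for t, w in raw.items()}
    return LossWeights(
        if_positive_class_weight=if_positive_class_weight, **fields
    )
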