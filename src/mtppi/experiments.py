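"""Comparative experiment designs.

Two designs are orchestrated on top of the dataset/training machinery:

* a task-combination sweep comparing the single-task interface model
  against multi-task variants (IFBU, IFBUSA, IFBUS3SA, ...) on the
  interface-annotated dataset and on its structurally extended superset;

* a label-scarcity curve: at each kept fraction of interface-annotated
  proteins, three strategies are trained on the *same* kept annotation
  set — the single-task model and the multi-task model on the annotated
  subset, and the multi-task model on the extended dataset — and all are
  evaluated on the identical full validation set.

All cells report mean +/- sample sd over independently seeded repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import (
    DatasetSplit,
    ProteinRecord,
    compute_class_weight,
    derive_ppi_split,
    kept_annotation_ids,
    mask_ppi_fraction,
    split_dataset,
)
from .evaluation import compare_auc_one_sided
from .loss import weight_scheme
from .model import build_model, tiny_config, variant_name
from .training import TrainingConfig, evaluate_model, train

MULTI_TASK_DEFAULT = ("IF", "BU", "S3", "SA")


@dataclass
class ExperimentPlan:
    """Desk-scale defaults: tiny model preset on synthetic-size corpora."""

    variants: Tuple[Tuple[str, ...], ...] = (("IF",), MULTI_TASK_DEFAULT)
    keep_fractions: Tuple[float, ...] = (1.0, 0.5, 0.125)
    n_repeats: int = 4
    base_seed: int = 0
    weight_method: str = "A"
    initial_lr: float = 2e-3
    batch_size: int = 16
    max_epochs: int = 20
    enhance: bool = False

    def __post_init__(self) -> None:
        for tasks in self.variants:
            if "IF" not in tasks:
                raise ValueError(f"every variant must include IF: {tasks}")
        for f in self.keep_fractions:
            if not 0 < f <= 1:
                raise ValueError(f"keep fraction {f} out of (0, 1]")


def _train_once(
    plan: ExperimentPlan,
    tasks: Sequence[str],
    train_records: Sequence[ProteinRecord],
    val_records: Sequence[ProteinRecord],
    seed: int,
) -> Dict[str, float]:
    """One training run; returns best-checkpoint validation metrics."""
    class_weight = compute_class_weight(list(train_records) + list(val_records))
    weights = weight_scheme(
        plan.weight_method, tasks, if_positive_class_weight=class_weight
    )
    model = build_model(tiny_config(tasks), seed=seed)
    config = TrainingConfig(
        initial_lr=plan.initial_lr,
        batch_size=plan.batch_size,
        max_epochs=plan.max_epochs,
        seed=seed,
        enhance=plan.enhance,
    )
    model, history = train(model, train_records, val_records, weights, config)
    report = evaluate_model(model, val_records)
    out = {
        "auc_roc": history.best_val_if_auc,
        "auc_pr": report.metrics["IF"].get("auc_pr") or np.nan,
    }
    return out


def _val_class_counts(val_records: Sequence[ProteinRecord]) -> Tuple[int, int]:
    pos = neg = 0
    for r in val_records:
        m = r.masks["IF"]
        y = np.asarray(r.labels["IF"])[m]
        pos += int((y == 1).sum())
        neg += int((y == 0).sum())
    return pos, neg


def make_splits(
    records: Sequence[ProteinRecord], seed: int
) -> Tuple[DatasetSplit, DatasetSplit]:
    """(PPI split, extended split) with per-partition subset consistency."""
    extended = split_dataset(records, seed=seed)
    return derive_ppi_split(extended), extended


def run_task_sweep(
    plan: ExperimentPlan, records: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Mean +/- sd interface AUC per (variant, dataset) over repeats.

    The single-task IF variant is the significance baseline: each row
    carries the one-sided p-value of its mean AUC against the
    single-task mean on the annotated dataset, using the validation
    class counts.
    """
    ppi_split, ext_split = make_splits(records, plan.base_seed)
    n_pos, n_neg = _val_class_counts(ext_split.validation)

    cells = []
    for tasks in plan.variants:
        name = variant_name(tasks)
        for ds_name, split in (("PPI", ppi_split),
                               ("PPI_extendedSFD", ext_split)):
            if name == "IF" and ds_name == "PPI_extendedSFD":
                # extension proteins carry no interface labels; a
                # single-task model cannot use them (identical cell)
                train_recs = ppi_split.train
            else:
                train_recs = split.train
            runs = [
                _train_once(plan, tasks, train_recs, ext_split.validation,
                            plan.base_seed + 1000 * r)
                for r in range(plan.n_repeats)
            ]
            aucs = np.array([r["auc_roc"] for r in runs])
            prs = np.array([r["auc_pr"] for r in runs])
            cells.append(
                {
                    "variant": name,
                    "dataset": ds_name,
                    "auc_roc_mean": aucs.mean(),
                    "auc_roc_sd": aucs.std(ddof=1),
                    "auc_pr_mean": prs.mean(),
                    "auc_pr_sd": prs.std(ddof=1),
                    "n_repeats": plan.n_repeats,
                }
            )
    table = pd.DataFrame(cells)

    base = table[(table.variant == "IF") & (table.dataset == "PPI")]
    base_auc = float(base.auc_roc_mean.iloc[0])
    pvals, stars = [], []
    for _, row in table.iterrows():
        p = compare_auc_one_sided(
            row.auc_roc_mean, n_pos, n_neg, base_auc, n_pos, n_neg
        )
        pvals.append(p)
        stars.append("**" if p < 1e-3 else "*" if p < 1e-2 else "")
    table["p_vs_single_task"] = pvals
    table["significance"] = stars
    return table


SCARCITY_STRATEGIES = (
    "single_task_ppi",
    "multi_task_ppi",
    "multi_task_extended",
)


def run_scarcity_curve(
    plan: ExperimentPlan,
    records: Sequence[ProteinRecord],
    multi_tasks: Sequence[str] = MULTI_TASK_DEFAULT,
) -> pd.DataFrame:
    """Interface AUC vs fraction of kept annotations for three strategies.

    At each fraction the kept-annotation protein set is identical across
    the three strategies (nested across fractions under the plan seed),
    and every strategy is evaluated on the same full validation set.
    """
    _, ext_split = make_splits(records, plan.base_seed)
    val_records = ext_split.validation
    mask_seed = plan.base_seed + 77

    cells = []
    for frac in plan.keep_fractions:
        kept = kept_annotation_ids(ext_split.train, frac, mask_seed)
        masked_train = mask_ppi_fraction(
            ext_split.train, frac, mask_seed, kept_ids=kept
        )
        kept_set = set(kept)
        kept_records = [
            r for r in masked_train if r.protein_id in kept_set
        ]
        strategy_data = {
            "single_task_ppi": (("IF",), kept_records),
            "multi_task_ppi": (tuple(multi_tasks), kept_records),
            "multi_task_extended": (tuple(multi_tasks), masked_train),
        }
        for strat, (tasks, train_recs) in strategy_data.items():
            runs = [
                _train_once(plan, tasks, train_recs, val_records,
                            plan.base_seed + 1000 * r)
                for r in range(plan.n_repeats)
            ]
            aucs = np.array([r["auc_roc"] for r in runs])
            cells.append(
                {
                    "keep_fraction": frac,
                    "strategy": strat,
                    "auc_roc_mean": aucs.mean(),
                    "auc_roc_sd": aucs.std(ddof=1),
                    "n_repeats": plan.n_repeats,
                    "n_kept_annotated": len(kept),
                    "n_train_proteins": len(train_recs),
                }
            )
    return pd.DataFrame(cells)
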