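"""Protein records, dataset assembly, splitting and annotation masking.

The central pairing of this package is between a fully structural dataset
and its interface-annotated subset: the *PPI dataset* holds proteins with
observed interface labels, and the *extended* dataset adds proteins that
carry only structural labels (secondary structure, accessibility,
buriedness). Interface annotations can further be reduced to a fraction
of proteins — masking whole proteins, never single residues — to study
label scarcity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import FeatureMatrix

TASKS = ("IF", "BU", "S3", "S8", "SA")


@dataclass
class ProteinRecord:
    """One chain: sequence, features, per-task labels and observation masks.

    ``masks[t]`` is True where task ``t``'s label is usable. An all-false
    interface mask means the protein carries no interface annotation.
    """

    protein_id: str
    sequence: str
    features: FeatureMatrix
    labels: Dict[str, np.ndarray]
    masks: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if self.features.length != L:
            raise ValueError(
                f"{self.protein_id}: feature length {self.features.length} "
                f"!= sequence length {L}"
            )
        for t in TASKS:
            if t not in self.labels or t not in self.masks:
                raise ValueError(f"{self.protein_id}: missing task {t}")
            if len(self.labels[t]) != L or len(self.masks[t]) != L:
                raise ValueError(f"{self.protein_id}: task {t} length mismatch")
            self.masks[t] = np.asarray(self.masks[t], dtype=bool)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_ppi_annotated(self) -> bool:
        return bool(self.masks["IF"].any())

    def copy(self) -> "ProteinRecord":
        return ProteinRecord(
            self.protein_id,
            self.sequence,
            FeatureMatrix(self.features.protein_id, self.features.values.copy()),
            {t: v.copy() for t, v in self.labels.items()},
            {t: v.copy() for t, v in self.masks.items()},
        )

    def with_if_masked(self) -> "ProteinRecord":
        """Copy with the whole interface vector masked; labels untouched."""
        out = self.copy()
        out.masks["IF"][:] = False
        return out

    def crop(self, start: int, stop: int) -> "ProteinRecord":
        """Contiguous fragment [start, stop) with labels and masks cropped."""
        if not 0 <= start < stop <= self.length:
            raise ValueError(f"invalid crop [{start}, {stop})")
        return ProteinRecord(
            self.protein_id,
            self.sequence[start:stop],
            FeatureMatrix(
                self.features.protein_id, self.features.values[start:stop]
            ),
            {t: v[start:stop].copy() for t, v in self.labels.items()},
            {t: v[start:stop].copy() for t, v in self.masks.items()},
        )


@dataclass
class DatasetSplit:
    train: List[ProteinRecord]
    validation: List[ProteinRecord]
    test: List[ProteinRecord]
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)

    def partitions(self) -> Dict[str, List[ProteinRecord]]:
        return {
            "train": self.train,
            "validation": self.validation,
            "test": self.test,
        }


def match_ppi_annotations(
    records: Sequence[ProteinRecord],
    ppi_table: pd.DataFrame,
) -> Tuple[List[ProteinRecord], Dict[str, int]]:
    """Attach per-residue interface labels by (PDB id + chain) key.

    ``ppi_table`` needs columns ``protein_id``, ``sequence`` and ``labels``
    (a 0/1 string, one character per residue). Labels are attached only
    when the annotation-source sequence equals the record sequence
    exactly; disagreeing entries are dropped (record kept, interface
    fully masked). Returns updated records plus a reconciliation report.
    """
    if ppi_table["protein_id"].duplicated().any():
        dups = ppi_table.loc[
            ppi_table["protein_id"].duplicated(), "protein_id"
        ].tolist()
        raise ValueError(f"duplicate keys in PPI table: {dups}")
    table = ppi_table.set_index("protein_id")

    report = {"matched": 0, "sequence_mismatch": 0, "unmatched": 0}
    out: List[ProteinRecord] = []
    for rec in records:
        rec = rec.copy()
        if rec.protein_id in table.index:
            row = table.loc[rec.protein_id]
            if row["sequence"] == rec.sequence:
                labels = np.fromiter(
                    (int(c) for c in row["labels"]), dtype=np.int8
                )
                rec.labels["IF"] = labels
                rec.masks["IF"] = np.ones(rec.length, dtype=bool)
                report["matched"] += 1
            else:
                rec.masks["IF"][:] = False
                report["sequence_mismatch"] += 1
        else:
            rec.masks["IF"][:] = False
            report["unmatched"] += 1
        out.append(rec)
    return out, report


def build_dataset_pair(
    records: Sequence[ProteinRecord],
) -> Tuple[List[ProteinRecord], List[ProteinRecord]]:
    """(PPI dataset, extended dataset): annotated subset vs everything."""
    ppi = [r for r in records if r.is_ppi_annotated]
    if not ppi:
        warnings.warn("no PPI-annotated proteins: PPI dataset is empty",
                      stacklevel=2)
    return ppi, list(records)


def split_dataset(
    records: Sequence[ProteinRecord],
    fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Random by-protein split, deterministic under ``seed``."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions {fractions} do not sum to 1")
    order = np.random.default_rng(seed).permutation(len(records))
    n = len(records)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    shuffled = [records[i] for i in order]
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
        fractions=fractions,
    )


def derive_ppi_split(extended_split: DatasetSplit) -> DatasetSplit:
    """PPI-dataset split reusing the extended split's partition assignment.

    Guarantees the per-partition strict-subset relation between the pair.
    """
    return DatasetSplit(
        train=[r for r in extended_split.train if r.is_ppi_annotated],
        validation=[
            r for r in extended_split.validation if r.is_ppi_annotated
        ],
        test=[r for r in extended_split.test if r.is_ppi_annotated],
        fractions=extended_split.fractions,
    )


def kept_annotation_ids(
    records: Sequence[ProteinRecord], keep_fraction: float, seed: int
) -> List[str]:
    """Protein ids retaining interface labels at ``keep_fraction``.

    Nested across fractions: for a fixed seed the kept set at a smaller
    fraction is a prefix (subset) of the kept set at a larger fraction.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError(f"keep_fraction {keep_fraction} out of (0, 1]")
    annotated = [r.protein_id for r in records if r.is_ppi_annotated]
    if not annotated:
        raise ValueError("no PPI-annotated proteins to keep")
    order = np.random.default_rng(seed).permutation(len(annotated))
    k = int(round(keep_fraction * len(annotated)))
    if k == 0:
        raise ValueError(
            f"keep_fraction {keep_fraction} leaves zero annotated proteins"
        )
    return [annotated[i] for i in order[:k]]


def mask_ppi_fraction(
    records: Sequence[ProteinRecord],
    keep_fraction: float,
    seed: int,
    kept_ids: Optional[Iterable[str]] = None,
) -> List[ProteinRecord]:
    """Retain interface labels for a random fraction of annotated proteins.

    Masking is per protein (never per residue), leaves structural labels
    untouched, never alters label values (unmasking is lossless) and is
    nested across fractions under a fixed seed. ``kept_ids`` overrides the
    random choice so several training strategies can share the identical
    annotation set.
    """
    if kept_ids is None:
        kept_ids = kept_annotation_ids(records, keep_fraction, seed)
    kept = set(kept_ids)
    out = []
    for rec in records:
        if rec.is_ppi_annotated and rec.protein_id not in kept:
            out.append(rec.with_if_masked())
        else:
            out.append(rec.copy())
    return out


def compute_class_weight(records: Sequence[ProteinRecord]) -> float:
    """Non-interface / interface residue ratio over observed positions.

    Computed over the supplied (training + validation) records, counting
    only residues whose interface label is observed.
    """
    n_pos = 0
    n_neg = 0
    for rec in records:
        m = rec.masks["IF"]
        labels = np.asarray(rec.labels["IF"])[m]
        n_pos += int((labels == 1).sum())
        n_neg += int((labels == 0).sum())
    if n_pos == 0:
        raise ValueError("no observed interface residues")
    return n_neg / n_pos


def write_manifest(
    split: DatasetSplit, path: str, extra: Optional[Dict] = None
) -> None:
    """JSON manifest listing partition membership and annotation state."""
    doc = {
        "fractions": list(split.fractions),
        "partitions": {
            name: [
                {
                    "protein_id": r.protein_id,
                    "length": r.length,
                    "ppi_annotated": r.is_ppi_annotated,
                }
                for r in part
            ]
            for name, part in split.partitions().items()
        },
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
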