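"""DSSP output parsing and per-residue gold-standard annotation.

Secondary structure (8- and 3-class), absolute solvent accessibility and
the derived buried label come from DSSP; interface labels come from the
inter-chain contact rule in :mod:`mtppi.structure`. Observation masks
record which labels may enter loss and metric computations: residues with
incomplete side chains are masked for SA and BU, and the whole interface
vector is masked when a protein carries no interface annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .constants import (
    BURIED_RSA_THRESHOLD,
    HEAVY_ATOM_COUNTS,
    MAX_ASA,
    S8_CLASSES,
    S8_TO_S3,
)
from .structure import StructureModel, compute_interface_labels


class DsspError(ValueError):
    """Raised for malformed DSSP files or structure/DSSP mismatches."""


@dataclass
class DsspRecord:
    chain_id: str
    residue_number: int
    amino_acid: str
    s8: str
    asa: float
    incomplete_side_chain: bool = False


@dataclass
class ResidueAnnotation:
    """Gold-standard labels for one residue; ``None`` marks missing.

    Invariants: ``buried`` is missing whenever ``asa`` is; when ``s8`` is
    present, ``s3`` equals its coarse class.
    """

    interface: Optional[int] = None
    buried: Optional[int] = None
    s3: Optional[str] = None
    s8: Optional[str] = None
    asa: Optional[float] = None


def map_s8_to_s3(s8: str) -> str:
    """Coarsen an 8-class DSSP code to coil ``C``/helix ``H``/strand ``E``."""
    try:
        return S8_TO_S3[s8]
    except KeyError:
        raise DsspError(f"unknown S8 class {s8!r}") from None


def compute_buried_label(asa: float, residue_name: str) -> int:
    """1 iff asa / maxASA(residue type) is strictly below 7%."""
    if asa < 0:
        raise ValueError(f"negative ASA {asa}")
    aa = residue_name if len(residue_name) == 1 else _three_to_one(residue_name)
    try:
        max_asa = MAX_ASA[aa]
    except KeyError:
        raise KeyError(f"no maximum ASA entry for residue {residue_name!r}") from None
    return int(asa / max_asa < BURIED_RSA_THRESHOLD)


def _three_to_one(name: str) -> str:
    from .constants import THREE_TO_ONE

    return THREE_TO_ONE.get(name.upper(), "X")


def parse_dssp(path: str) -> Dict[str, List[DsspRecord]]:
    """Parse a classic fixed-column DSSP output file.

    Returns an ordered dict chain_id -> residue records. Chain-break lines
    (``!`` in the amino-acid column) emit no record; a blank structure
    column maps to coil. The ``incomplete_side_chain`` flag is not stored
    in DSSP output; it defaults to False here and is determined from the
    coordinate file in :func:`build_annotations`.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise DsspError(f"{path}: missing '#  RESIDUE' data header")

    chains: Dict[str, List[DsspRecord]] = {}
    for line in lines[start:]:
        if len(line) < 38 or not line.strip():
            continue
        aa = line[13]
        if aa == "!":  # chain break / chain terminator
            continue
        if aa.islower():  # disulfide-bridged cysteine convention
            aa = "C"
        chain_id = line[11].strip() or "A"
        try:
            resnum = int(line[5:10])
            acc = float(line[34:38])
        except ValueError as exc:
            raise DsspError(f"{path}: unparsable DSSP line: {line!r}") from exc
        ss = line[16]
        if ss == " ":
            ss = "C"
        elif ss == "P":  # polyproline-II code of newer DSSP versions
            ss = "C"
        if ss not in S8_CLASSES:
            raise DsspError(f"{path}: unknown structure code {ss!r}")
        chains.setdefault(chain_id, []).append(
            DsspRecord(chain_id, resnum, aa, ss, acc)
        )
    if not chains:
        raise DsspError(f"{path}: no residue records")
    return chains


@dataclass
class ChainAnnotations:
    chain_id: str
    annotations: List[ResidueAnnotation]
    masks: Dict[str, np.ndarray]  # task -> bool vector, True = observed

    def label_array(self, task: str) -> np.ndarray:
        """Dense label vector with unobserved positions zero-filled."""
        vals = []
        for ann, obs in zip(self.annotations, self.masks[task]):
            v = {
                "IF": ann.interface,
                "BU": ann.buried,
                "S3": None if ann.s3 is None else "CHE".index(ann.s3),
                "S8": None if ann.s8 is None else S8_CLASSES.index(ann.s8),
                "SA": ann.asa,
            }[task]
            vals.append(0.0 if (v is None or not obs) else float(v))
        return np.asarray(vals)


def _incomplete_side_chain(residue) -> bool:
    aa = residue.one_letter
    expected = HEAVY_ATOM_COUNTS.get(aa)
    if expected is None:
        return True  # non-standard residue: be conservative, mask SA/BU
    n_heavy = sum(1 for a in residue.atoms if a.element != "H")
    return n_heavy < expected


TASKS = ("IF", "BU", "S3", "S8", "SA")


def build_annotations(
    structure: StructureModel,
    dssp: Dict[str, List[DsspRecord]],
    ppi_available: bool = True,
    pad: float = 0.5,
    radii=None,
) -> Dict[str, ChainAnnotations]:
    """Combine structure and DSSP into per-residue labels plus masks.

    Masking rules: residues with incomplete side chains are masked for the
    SA and BU tasks; when ``ppi_available`` is False (or the structure has
    a single chain) the entire interface vector is masked. Masked residues
    never enter loss or performance computations downstream.
    """
    if ppi_available and len(structure.chains) >= 2:
        iface = compute_interface_labels(structure, pad=pad, radii=radii)
    else:
        iface = {c.chain_id: None for c in structure.chains}

    out: Dict[str, ChainAnnotations] = {}
    for chain in structure.chains:
        records = dssp.get(chain.chain_id)
        if records is None:
            raise DsspError(f"chain {chain.chain_id} absent from DSSP file")
        if len(records) != len(chain.residues):
            raise DsspError(
                f"chain {chain.chain_id}: {len(chain.residues)} structure "
                f"residues vs {len(records)} DSSP records"
            )
        n = len(chain.residues)
        masks = {t: np.ones(n, dtype=bool) for t in TASKS}
        anns: List[ResidueAnnotation] = []
        chain_iface = iface[chain.chain_id]
        if chain_iface is None:
            masks["IF"][:] = False
        for i, (res, rec) in enumerate(zip(chain.residues, records)):
            if rec.amino_acid not in ("X", res.one_letter):
                raise DsspError(
                    f"chain {chain.chain_id} position {i}: structure residue "
                    f"{res.one_letter} vs DSSP {rec.amino_acid}"
                )
            ann = ResidueAnnotation(s8=rec.s8, s3=map_s8_to_s3(rec.s8))
            incomplete = rec.incomplete_side_chain or _incomplete_side_chain(res)
            if incomplete:
                masks["SA"][i] = False
                masks["BU"][i] = False
            else:
                ann.asa = rec.asa
                ann.buried = compute_buried_label(rec.asa, res.one_letter)
            if chain_iface is not None:
                ann.interface = int(chain_iface[i])
            anns.append(ann)
        out[chain.chain_id] = ChainAnnotations(chain.chain_id, anns, masks)
    return out


def write_annotation_tsv(
    structure: StructureModel,
    annotations: Dict[str, ChainAnnotations],
    path: str,
) -> None:
    """Write per-residue labels as TSV; missing values rendered as '.'."""

    def fmt(v):
        if v is None:
            return "."
        if isinstance(v, float):
            return f"{v:g}"
        return str(v)

    with open(path, "w") as fh:
        fh.write(
            "chain_id\tresidue_index\tresidue_name\tIF\tBU\tS3\tS8\tSA"
            "\tmask_IF\tmask_SA\n"
        )
        for chain in structure.chains:
            ca = annotations[chain.chain_id]
            for i, (res, ann) in enumerate(zip(chain.residues, ca.annotations)):
                row = [
                    chain.chain_id,
                    str(i),
                    res.residue_name,
                    fmt(ann.interface),
                    fmt(ann.buried),
                    fmt(ann.s3),
                    fmt(ann.s8),
                    fmt(ann.asa),
                    str(int(ca.masks["IF"][i])),
                    str(int(ca.masks["SA"][i])),
                ]
                fh.write("\t".join(row) + "\n")
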