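"""76-dimensional per-residue input features.

Per residue the encoder concatenates four blocks in fixed order:
20 PSSM log-odds (PSI-BLAST ascii profile), 30 HMM profile values
(HHblits HHM: 20 match emissions + 7 transition frequencies + 3 local
diversity values), 7 physicochemical descriptors (Meiler) and the 19
binary rigid-block indicators. The last two blocks are pure functions of
the residue identity; the first two carry the evolutionary signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import h5py
import numpy as np

from .constants import MEILER7, MEILER7_MEAN, PSP19

#: Fixed column layout of the 76-feature matrix.
COLUMN_BLOCKS: Dict[str, Tuple[int, int]] = {
    "PSSM": (0, 20),
    "HMM": (20, 50),
    "PHYS7": (50, 57),
    "PSP19": (57, 76),
}
N_FEATURES = 76


class ProfileError(ValueError):
    """Raised for malformed or mismatching PSSM/HHM profile files."""


@dataclass
class FeatureMatrix:
    protein_id: str
    values: np.ndarray  # (length, 76) float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must have {N_FEATURES} columns, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def block(self, name: str) -> np.ndarray:
        lo, hi = COLUMN_BLOCKS[name]
        return self.values[:, lo:hi]


def parse_pssm(path: str, sequence: str) -> np.ndarray:
    """Read the 20 log-odds columns of a PSI-BLAST ascii PSSM.

    The file's residue column must match ``sequence`` exactly. Values are
    returned as raw log-odds in the file's amino-acid column order.
    """
    rows = []
    residues = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 22 and parts[0].isdigit() and parts[1].isalpha() \
                    and len(parts[1]) == 1:
                try:
                    vals = [float(x) for x in parts[2:22]]
                except ValueError:
                    continue  # header line with two alphabet repeats
                residues.append(parts[1])
                rows.append(vals)
    if not rows:
        raise ProfileError(f"{path}: no PSSM rows found")
    if len(rows) != len(sequence) or "".join(residues) != sequence:
        raise ProfileError(
            f"{path}: PSSM residue column {''.join(residues)!r} does not "
            f"match sequence {sequence!r}"
        )
    return np.asarray(rows, dtype=float)


def _hhm_value(token: str) -> float:
    """HHM score transform: integer x -> 2^(-x/1000); '*' -> 0."""
    if token == "*":
        return 0.0
    return float(2.0 ** (-int(token) / 1000.0))


def parse_hhm(path: str, sequence: str) -> np.ndarray:
    """Read the 30 per-residue profile values of an HHblits HHM file.

    Per residue: 20 match-emission probabilities followed by the 10
    transition/diversity values, all transformed by ``2^(-x/1000)`` with
    ``*`` mapping to 0.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]

    start = None
    for i, ln in enumerate(lines):
        if ln.startswith("HMM "):
            start = i + 3  # skip the two header rows and the null-model row
            break
    if start is None:
        raise ProfileError(f"{path}: missing 'HMM' block delimiter")

    emissions, transitions, residues = [], [], []
    i = start
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("//"):
            break
        parts = ln.split()
        if len(parts) >= 22 and len(parts[0]) == 1 and parts[0].isalpha():
            residues.append(parts[0])
            emissions.append([_hhm_value(t) for t in parts[2:22]])
            trans = lines[i + 1].split()
            if len(trans) < 10:
                raise ProfileError(f"{path}: truncated transition line")
            transitions.append([_hhm_value(t) for t in trans[:10]])
            i += 2
        else:
            i += 1
    if not emissions:
        raise ProfileError(f"{path}: no residue rows in HMM block")
    if len(emissions) != len(sequence) or "".join(residues) != sequence:
        raise ProfileError(
            f"{path}: HHM residue column does not match sequence"
        )
    return np.concatenate(
        [np.asarray(emissions, float), np.asarray(transitions, float)], axis=1
    )


def physchem_features(sequence: str) -> np.ndarray:
    """(L, 7) Meiler descriptor matrix; residue-determined, protein free.

    Unknown residues (e.g. 'X') receive the mean of the 20 canonical rows.
    """
    rows = [MEILER7.get(aa, MEILER7_MEAN) for aa in sequence]
    return np.asarray(rows, dtype=float)


def psp19_features(sequence: str) -> np.ndarray:
    """(L, 19) binary rigid-block indicator matrix.

    Each row marks which side-chain rigid blocks the residue contains;
    unknown residues yield an all-zero row.
    """
    zero = np.zeros(19, dtype=np.int8)
    rows = [PSP19.get(aa, zero) for aa in sequence]
    return np.asarray(rows, dtype=float)


def encode_protein(
    sequence: str,
    pssm_path: Optional[str] = None,
    hhm_path: Optional[str] = None,
    protein_id: str = "protein",
    pssm: Optional[np.ndarray] = None,
    hhm: Optional[np.ndarray] = None,
    pssm_normalize: str = "raw",
    zscore: bool = False,
) -> FeatureMatrix:
    """Assemble the L x 76 feature matrix in block order PSSM|HMM|PHYS7|PSP19.

    Profiles may be given as file paths or as pre-parsed arrays. With
    ``pssm_normalize="sigmoid"`` the log-odds block is squashed through a
    logistic; ``zscore=True`` standardizes the PSSM and HMM columns
    (both off by default).
    """
    if pssm is None:
        if pssm_path is None:
            raise ValueError("either pssm or pssm_path is required")
        pssm = parse_pssm(pssm_path, sequence)
    if hhm is None:
        if hhm_path is None:
            raise ValueError("either hhm or hhm_path is required")
        hhm = parse_hhm(hhm_path, sequence)
    pssm = np.asarray(pssm, dtype=float)
    hhm = np.asarray(hhm, dtype=float)
    L = len(sequence)
    if pssm.shape != (L, 20):
        raise ProfileError(f"PSSM block shape {pssm.shape}, expected ({L}, 20)")
    if hhm.shape != (L, 30):
        raise ProfileError(f"HMM block shape {hhm.shape}, expected ({L}, 30)")
    if pssm_normalize == "sigmoid":
        pssm = 1.0 / (1.0 + np.exp(-pssm))
    elif pssm_normalize != "raw":
        raise ValueError(f"unknown pssm_normalize {pssm_normalize!r}")
    if zscore:
        for blk in (pssm, hhm):
            sd = blk.std(axis=0)
            sd[sd == 0] = 1.0
            blk -= blk.mean(axis=0)
            blk /= sd
    values = np.concatenate(
        [pssm, hhm, physchem_features(sequence), psp19_features(sequence)],
        axis=1,
    )
    return FeatureMatrix(protein_id, values)


def save_features(features: Dict[str, FeatureMatrix], path: str) -> None:
    """Store feature matrices in an HDF5 container (one dataset per protein)."""
    with h5py.File(path, "w") as fh:
        for pid, fm in features.items():
            fh.create_dataset(pid, data=fm.values)


def load_features(path: str) -> Dict[str, FeatureMatrix]:
    out = {}
    with h5py.File(path, "r") as fh:
        for pid in fh:
            out[pid] = FeatureMatrix(pid, fh[pid][()])
    return out
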