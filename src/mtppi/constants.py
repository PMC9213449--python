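"""Embedded reference tables used across the package.

All tables are keyed by one-letter or element codes and are deliberately
small, auditable and overridable where the public API allows it.
"""

from __future__ import annotations

import numpy as np

#: Canonical one-letter amino-acid alphabet (alphabetical by letter).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Element-keyed van der Waals radii in Angstrom used by the inter-chain
#: contact criterion (distance < r_a + r_b + pad). Overridable via the
#: ``radii`` argument of the interface labeling routines; lookup of an
#: element absent from the table is an explicit error.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.20,
}

#: Theoretical maximum solvent accessibility per residue type (Tien et al.
#: 2013, theoretical values), in Angstrom^2. Used to normalize absolute ASA
#: for the 7% buried-residue rule.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Fraction of maximum accessibility below which a residue counts as buried
#: (strict less-than).
BURIED_RSA_THRESHOLD = 0.07

#: Canonical heavy-atom counts (backbone N, CA, C, O plus side chain).
#: A residue observed with fewer heavy atoms has an incomplete side chain
#: and is masked for the solvent-accessibility and buried tasks.
HEAVY_ATOM_COUNTS = {
    "G": 4, "A": 5, "S": 6, "C": 6, "T": 7, "V": 7, "P": 7,
    "L": 8, "I": 8, "N": 8, "D": 8, "M": 8,
    "Q": 9, "E": 9, "K": 9, "H": 10, "R": 11, "F": 11,
    "Y": 12, "W": 14,
}

# ---------------------------------------------------------------------------
# Secondary structure

#: The eight DSSP secondary-structure classes. "C" stands for the blank
#: (loop/irregular) DSSP code; "S" is bend/high-curvature, "T" beta-turn,
#: "B" beta-bridge, "G" 3-10 helix, "I" pi-helix.
S8_CLASSES = ("H", "G", "I", "E", "B", "T", "S", "C")

S3_CLASSES = ("C", "H", "E")  # coil, helix, strand

#: Partition of the eight DSSP classes into the three coarse classes:
#: {coil, high-curvature, beta-turn} -> coil, {alpha, 3-10, pi helix} ->
#: helix, {strand, bridge} -> strand.
S8_TO_S3 = {
    "C": "C", "S": "C", "T": "C",
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
}

# ---------------------------------------------------------------------------
# Sequence-only feature tables

#: The seven Meiler descriptors per amino acid: steric parameter,
#: polarizability, volume, hydrophobicity, isoelectric point, helix
#: propensity, sheet propensity. Protein independent, residue specific.
MEILER7 = {
    "A": (1.28, 0.05, 1.00, 0.31, 6.11, 0.42, 0.23),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35, 0.17, 0.41),
    "D": (1.60, 0.11, 2.78, -0.77, 2.95, 0.25, 0.20),
    "E": (1.56, 0.15, 3.78, -0.64, 3.09, 0.42, 0.21),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67, 0.30, 0.38),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "H": (2.99, 0.23, 4.66, 0.13, 7.69, 0.27, 0.30),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04, 0.30, 0.45),
    "K": (1.89, 0.22, 4.77, -0.99, 9.99, 0.32, 0.27),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04, 0.39, 0.31),
    "M": (2.35, 0.22, 4.43, 1.23, 5.71, 0.38, 0.32),
    "N": (1.60, 0.13, 2.95, -0.60, 6.52, 0.21, 0.22),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80, 0.13, 0.34),
    "Q": (1.56, 0.18, 3.95, -0.22, 5.65, 0.36, 0.25),
    "R": (2.34, 0.29, 6.13, -1.01, 10.74, 0.36, 0.25),
    "S": (1.31, 0.06, 1.60, -0.04, 5.70, 0.20, 0.28),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60, 0.21, 0.36),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02, 0.27, 0.49),
    "W": (3.21, 0.41, 8.08, 2.25, 5.94, 0.32, 0.42),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66, 0.25, 0.41),
}

#: Rigid-block membership encoding of side-chain composition ("PSP"-style),
#: 19 binary indicators per residue marking which rigid side-chain fragments
#: the residue contains. The block inventory is a chemically motivated
#: fragment decomposition (backbone peptide unit, methyl, methylenes,
#: branched CH, hydroxyl, thiol, thioether, carboxylate, amide, guanidinium,
#: amine, aromatic ring systems, pyrrolidine, chain-length markers).
#: Binary, protein independent, residue determined; glycine carries only the
#: backbone block.
PSP19_BLOCKS = (
    "backbone", "methyl", "beta_methylene", "aliphatic_ch", "hydroxyl",
    "thiol", "thioether", "carboxylate", "amide", "guanidinium",
    "amine", "benzene", "imidazole", "indole", "pyrrolidine",
    "gamma_methylene", "delta_methylene", "beta_branch", "long_chain",
)

_PSP19_MEMBERSHIP = {
    "backbone": AMINO_ACIDS,
    "methyl": "AILMTV",
    "beta_methylene": "RNDCEQHIKLMFPSWY",
    "aliphatic_ch": "ILTV",
    "hydroxyl": "STY",
    "thiol": "C",
    "thioether": "M",
    "carboxylate": "DE",
    "amide": "NQ",
    "guanidinium": "R",
    "amine": "K",
    "benzene": "FY",
    "imidazole": "H",
    "indole": "W",
    "pyrrolidine": "P",
    "gamma_methylene": "REQKMP",
    "delta_methylene": "RK",
    "beta_branch": "IVT",
    "long_chain": "RKMEQ",
}


def _build_psp19() -> dict[str, np.ndarray]:
    table = {}
    for aa in AMINO_ACIDS:
        row = np.zeros(19, dtype=np.int8)
        for j, block in enumerate(PSP19_BLOCKS):
            if aa in _PSP19_MEMBERSHIP[block]:
                row[j] = 1
        table[aa] = row
    return table


PSP19 = _build_psp19()

#: Mean of the 20 canonical Meiler rows, used for the unknown residue 'X'.
MEILER7_MEAN = tuple(
    float(np.mean([MEILER7[aa][j] for aa in AMINO_ACIDS])) for j in range(7)
)
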