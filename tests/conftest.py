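"""Shared fixtures: tiny hand-written file fixtures and synthetic corpora."""

from __future__ import annotations

import numpy as np
import pytest

from mtppi.synthetic import SyntheticParams, generate_dataset


def pdb_atom_line(serial, name, resname, chain, resnum, x, y, z,
                  occ=1.0, element="C", altloc=" "):
    return (
        f"ATOM  {serial:>5d} {name:<4s}{altloc}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}\n"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Single chain, three CA-only glycines plus one water (to be excluded)."""
    lines = [
        pdb_atom_line(1, " CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, " CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        pdb_atom_line(3, " CA", "GLY", "A", 3, 7.6, 0.0, 0.0),
        "HETATM    4  O   HOH A   4      20.000  20.000  20.000  1.00  0.00           O\n",
        "END\n",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Two 3-residue chains; closest inter-chain C-C pair at 3.85 A.

    With carbon radius 1.7 and pad 0.5 the contact threshold is 3.9 A, so
    exactly residue 2 of A and residue 1 of B touch.
    """
    lines = [
        pdb_atom_line(1, " CA", "GLY", "A", 1, 0.0, 0.0, 0.0),
        pdb_atom_line(2, " CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        pdb_atom_line(3, " CA", "GLY", "A", 3, 7.6, 0.0, 0.0),
        pdb_atom_line(4, " CA", "GLY", "B", 1, 3.8, 3.85, 0.0),
        pdb_atom_line(5, " CA", "GLY", "B", 2, 7.6, 3.85 + 8.0, 0.0),
        pdb_atom_line(6, " CA", "GLY", "B", 3, 11.4, 3.85 + 16.0, 0.0),
        "END\n",
    ]
    path = tmp_path / "pair.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """One atom in two alternate locations, occupancies 0.6 (A) and 0.4 (B)."""
    lines = [
        pdb_atom_line(1, " CA", "GLY", "A", 1, 0.0, 0.0, 0.0, occ=0.6,
                      altloc="A"),
        pdb_atom_line(2, " CA", "GLY", "A", 1, 1.0, 0.0, 0.0, occ=0.4,
                      altloc="B"),
        pdb_atom_line(3, " CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        "END\n",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("".join(lines))
    return path


def dssp_line(serial, resnum, chain, aa, ss, acc):
    head = f"{serial:5d}{resnum:5d} {chain} {aa}  {ss}"
    return head + " " * (34 - len(head)) + f"{acc:4d}\n"


DSSP_HEADER = (
    "==== Secondary Structure Definition by the program DSSP ====\n"
    "REFERENCE ...\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N\n"
)


@pytest.fixture
def simple_dssp(tmp_path):
    """Three residues: helix with ACC 120, blank SS, strand; then a chain
    break and a second chain with one coil residue."""
    body = (
        dssp_line(1, 1, "A", "G", "H", 120)
        + dssp_line(2, 2, "A", "G", " ", 30)
        + dssp_line(3, 3, "A", "G", "E", 5)
        + f"{4:5d}" + " " * 8 + "!" + " " * 20 + "   0\n"
        + dssp_line(5, 1, "B", "A", "T", 88)
    )
    path = tmp_path / "simple.dssp"
    path.write_text(DSSP_HEADER + body)
    return path


PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


def make_pssm_text(sequence, matrix):
    header = (
        "\nLast position-specific scoring matrix computed\n"
        "            " + "   ".join(PSSM_ALPHABET) + "   "
        + "   ".join(PSSM_ALPHABET) + "\n"
    )
    rows = []
    for i, (aa, vals) in enumerate(zip(sequence, matrix), start=1):
        nums = " ".join(f"{int(v):3d}" for v in vals)
        pct = " ".join("  0" for _ in range(20))
        rows.append(f"{i:5d} {aa}  {nums} {pct}  0.30 0.09\n")
    return header + "".join(rows) + "\n"


@pytest.fixture
def pssm_fixture(tmp_path):
    sequence = "ACD"
    matrix = np.arange(60).reshape(3, 20) - 30
    path = tmp_path / "test.pssm"
    path.write_text(make_pssm_text(sequence, matrix))
    return path, sequence, matrix.astype(float)


def make_hhm_text(sequence, emission_scores, transition_scores):
    """emission/transition scores: per-residue lists of 20/10 tokens."""
    lines = [
        "HHsearch 1.5\nNAME  fixture\nLENG  %d\n" % len(sequence),
        "HMM    A\tC\tD\tE\tF\tG\tH\tI\tK\tL\tM\tN\tP\tQ\tR\tS\tT\tV\tW\tY\n",
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D\n",
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*\n",
    ]
    for i, aa in enumerate(sequence):
        em = "\t".join(str(t) for t in emission_scores[i])
        tr = "\t".join(str(t) for t in transition_scores[i])
        lines.append(f"{aa} {i + 1}    {em}\t{i + 1}\n")
        lines.append(f"       {tr}\n")
    lines.append("//\n")
    return "".join(lines)


@pytest.fixture
def hhm_fixture(tmp_path):
    sequence = "ACD"
    emissions = [
        ["0"] + ["*"] * 19,
        ["1000"] * 20,
        ["2000"] + ["*"] * 19,
    ]
    transitions = [
        ["0", "*", "*", "0", "*", "0", "*", "1000", "0", "0"],
        ["*"] * 10,
        ["1000"] * 10,
    ]
    path = tmp_path / "test.hhm"
    path.write_text(make_hhm_text(sequence, emissions, transitions))
    return path, sequence, emissions, transitions


@pytest.fixture(scope="session")
def small_dataset():
    """60-protein synthetic corpus shared across tests (read-only)."""
    return generate_dataset(SyntheticParams(n_proteins=60, seed=11))


@pytest.fixture(scope="session")
def medium_dataset():
    """200-protein corpus for statistical checks (read-only)."""
    return generate_dataset(SyntheticParams(n_proteins=200, seed=7))
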