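"""Multi-chain structure parsing and inter-chain interface labeling.

A residue is an interface residue when any of its atoms lies within
``r_vdw(a) + r_vdw(b) + pad`` Angstrom (default pad 0.5) of an atom of a
residue in a *different* chain. Labels are symmetric by construction: the
partner residue is labeled as well. Structures with a single protein chain
have no defined interface; every label is reported missing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .constants import THREE_TO_ONE, VDW_RADII


class StructureError(ValueError):
    """Raised for unreadable or protein-free coordinate files."""


class UnknownElementError(KeyError):
    """Raised when an atom's element has no van der Waals radius entry."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: non-finite coordinates")


@dataclass
class Residue:
    residue_number: int  # author numbering, preserved for reporting
    residue_name: str  # 3-letter code
    atoms: List[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.residue_name, "X")


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class StructureModel:
    structure_id: str
    chains: List[Chain] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate chain ids in {self.structure_id}")

    @property
    def chain_ids(self) -> List[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


def _is_amino_acid(name: str) -> bool:
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def parse_structure(path: str, fmt: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Heteroatoms and waters are excluded; alternate locations are resolved
    to the highest-occupancy conformer (per atom name). Only the first
    model of multi-model files is used.

    Parameters
    ----------
    path:
        Coordinate file; format inferred from the extension unless ``fmt``
        (``"pdb"`` or ``"cif"``) is given.
    """
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("cif", "mmcif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"unreadable coordinate file {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]

    chains: List[Chain] = []
    for gchain in model:
        residues: List[Residue] = []
        for gres in gchain:
            if not _is_amino_acid(gres.name):
                continue  # waters, ligands, nucleic acids
            # resolve altlocs: per atom name keep the highest occupancy
            best: Dict[str, gemmi.Atom] = {}
            for atom in gres:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = [
                Atom(a.name, a.element.name.upper(),
                     np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in best.values()
            ]
            if atoms:
                residues.append(Residue(gres.seqid.num, gres.name, atoms))
        if residues:
            chains.append(Chain(gchain.name, residues))

    if not chains:
        raise StructureError(f"{path}: no protein chains")
    return StructureModel(st.name or "structure", chains)


def _chain_arrays(chain: Chain, radii: Dict[str, float]):
    coords, rads, res_idx = [], [], []
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            try:
                rads.append(radii[atom.element])
            except KeyError as exc:
                raise UnknownElementError(
                    f"no van der Waals radius for element {atom.element!r} "
                    f"(chain {chain.chain_id}, residue {res.residue_name} "
                    f"{res.residue_number})"
                ) from exc
            coords.append(atom.coords)
            res_idx.append(i)
    return (np.asarray(coords, dtype=float),
            np.asarray(rads, dtype=float),
            np.asarray(res_idx, dtype=int))


def compute_interface_labels(
    structure: StructureModel,
    pad: float = 0.5,
    radii: Optional[Dict[str, float]] = None,
) -> Dict[str, Optional[np.ndarray]]:
    """Per-chain binary interface label vectors.

    Residue ``r`` of chain ``c`` is labeled 1 iff some atom of ``r`` is
    within ``radius(a) + radius(b) + pad`` of an atom ``b`` of a residue in
    a different chain; the residue containing ``b`` is labeled as well.

    Returns a dict chain_id -> int8 vector. For a single-chain structure
    the interface is undefined: a warning is issued and every chain maps
    to ``None`` (all labels missing).

    Inter-chain contacts are found with one KD-tree per chain; the exact
    per-pair threshold is applied on the candidate pairs.
    """
    radii = dict(VDW_RADII if radii is None else radii)
    for el, r in radii.items():
        if not r > 0:
            raise ValueError(f"non-positive vdW radius for {el}")

    if len(structure.chains) < 2:
        warnings.warn(
            f"{structure.structure_id}: single-chain structure, interface "
            "labels are undefined (all missing)",
            stacklevel=2,
        )
        return {c.chain_id: None for c in structure.chains}

    per_chain = [_chain_arrays(c, radii) for c in structure.chains]
    labels = {
        c.chain_id: np.zeros(len(c), dtype=np.int8) for c in structure.chains
    }
    trees = [cKDTree(coords) for coords, _, _ in per_chain]
    max_r = [rads.max() if rads.size else 0.0 for _, rads, _ in per_chain]

    for i in range(len(structure.chains)):
        coords_i, rads_i, res_i = per_chain[i]
        for j in range(i + 1, len(structure.chains)):
            coords_j, rads_j, res_j = per_chain[j]
            upper = max_r[i] + max_r[j] + pad
            pairs = trees[i].query_ball_tree(trees[j], r=upper)
            for ai, neigh in enumerate(pairs):
                if not neigh:
                    continue
                neigh = np.asarray(neigh, dtype=int)
                d = np.linalg.norm(coords_j[neigh] - coords_i[ai], axis=1)
                hit = d < rads_i[ai] + rads_j[neigh] + pad
                if np.any(hit):
                    labels[structure.chains[i].chain_id][res_i[ai]] = 1
                    for bj in neigh[hit]:
                        labels[structure.chains[j].chain_id][res_j[bj]] = 1
    return labels


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def shrake_rupley_asa(
    structure: StructureModel,
    probe: float = 1.4,
    n_points: int = 92,
    radii: Optional[Dict[str, float]] = None,
) -> Dict[str, np.ndarray]:
    """Per-residue accessible surface area (Angstrom^2), Shrake-Rupley.

    Each atom's solvent-expanded sphere (vdW radius + probe) is sampled at
    ``n_points`` quasi-uniform points; the accessible fraction is the share
    of points outside every neighboring atom's expanded sphere. Per-residue
    ASA is the sum over the residue's atoms. Intended for desk-scale
    fixtures and synthetic data; DSSP files are the primary accessibility
    source for real structures.
    """
    radii = dict(VDW_RADII if radii is None else radii)
    sphere = _fibonacci_sphere(n_points)

    coords, rads, owner = [], [], []  # owner: (chain_index, residue_index)
    for ci, chain in enumerate(structure.chains):
        c_coords, c_rads, c_res = _chain_arrays(chain, radii)
        coords.append(c_coords)
        rads.append(c_rads)
        owner.append(np.stack([np.full_like(c_res, ci), c_res], axis=1))
    coords = np.concatenate(coords)
    rads = np.concatenate(rads)
    owner = np.concatenate(owner)

    expanded = rads + probe
    tree = cKDTree(coords)
    out = {
        c.chain_id: np.zeros(len(c), dtype=float) for c in structure.chains
    }
    max_reach = 2.0 * expanded.max()
    for a in range(len(coords)):
        pts = coords[a] + expanded[a] * sphere
        neigh = [n for n in tree.query_ball_point(coords[a], max_reach)
                 if n != a]
        accessible = np.ones(n_points, dtype=bool)
        for n in neigh:
            d = np.linalg.norm(pts - coords[n], axis=1)
            accessible &= d >= expanded[n]
        frac = accessible.mean()
        area = 4.0 * math.pi * expanded[a] ** 2 * frac
        ci, ri = owner[a]
        out[structure.chains[ci].chain_id][ri] += area
    return out
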