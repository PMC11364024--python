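"""Atomic (and pseudo-atomic) models for scattering calculations.

Two resolutions are supported by the same container:

* heavy-atom models from PDB files, with implicit hydrogens assigned per
  residue/atom-name templates (deposited coil models carry no hydrogens);
* coarse one-bead-per-residue chains whose beads carry the residue's full
  electron count (used by the synthetic generator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError
from .residues import RESIDUE_ELECTRONS, THREE_TO_ONE

__all__ = ["AtomicModel", "load_pdb", "implicit_hydrogens"]

KNOWN_ELEMENTS = {"H", "C", "N", "O", "S", "P"}

ELEMENT_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15}

#: van der Waals radii (A), for surface-accessibility tests.
VDW_RADIUS = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
              "P": 1.80, "X": 1.90}

# Implicit hydrogen counts per residue and heavy-atom name.  Backbone N
# carries one H (none for proline), CA one (two for glycine); carbonyl C and
# O none.  Ionizable groups are taken in their pH ~7 forms.
_BACKBONE_H = {"N": 1, "CA": 1, "C": 0, "O": 0, "OXT": 0}
_SIDECHAIN_H = {
    "ALA": {"CB": 3},
    "ARG": {"CB": 2, "CG": 2, "CD": 2, "NE": 1, "CZ": 0, "NH1": 2, "NH2": 2},
    "ASN": {"CB": 2, "CG": 0, "OD1": 0, "ND2": 2},
    "ASP": {"CB": 2, "CG": 0, "OD1": 0, "OD2": 0},
    "CYS": {"CB": 2, "SG": 1},
    "GLN": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "NE2": 2},
    "GLU": {"CB": 2, "CG": 2, "CD": 0, "OE1": 0, "OE2": 0},
    "GLY": {},
    "HIS": {"CB": 2, "CG": 0, "ND1": 1, "CD2": 1, "CE1": 1, "NE2": 0},
    "ILE": {"CB": 1, "CG1": 2, "CG2": 3, "CD1": 3},
    "LEU": {"CB": 2, "CG": 1, "CD1": 3, "CD2": 3},
    "LYS": {"CB": 2, "CG": 2, "CD": 2, "CE": 2, "NZ": 3},
    "MET": {"CB": 2, "CG": 2, "SD": 0, "CE": 3},
    "PHE": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1, "CZ": 1},
    "PRO": {"CB": 2, "CG": 2, "CD": 2},
    "SER": {"CB": 2, "OG": 1},
    "THR": {"CB": 1, "OG1": 1, "CG2": 3},
    "TRP": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 0, "NE1": 1, "CE2": 0,
            "CE3": 1, "CZ2": 1, "CZ3": 1, "CH2": 1},
    "TYR": {"CB": 2, "CG": 0, "CD1": 1, "CD2": 1, "CE1": 1, "CE2": 1,
            "CZ": 0, "OH": 1},
    "VAL": {"CB": 1, "CG1": 3, "CG2": 3},
}


def implicit_hydrogens(resname: str, atom_name: str) -> int:
    """Implicit H count for a heavy atom, from residue/atom-name templates."""
    resname = resname.upper()
    atom_name = atom_name.upper()
    if resname == "GLY" and atom_name == "CA":
        return 2
    if resname == "PRO" and atom_name == "N":
        return 0
    if atom_name in _BACKBONE_H:
        return _BACKBONE_H[atom_name]
    table = _SIDECHAIN_H.get(resname)
    if table is not None and atom_name in table:
        return table[atom_name]
    warnings.warn(f"no hydrogen template for {resname}/{atom_name}; assuming 0")
    return 0


@dataclass
class AtomicModel:
    """Point-scatterer model: coordinates plus per-atom identity.

    ``elements`` uses chemical symbols for real atoms and ``"X"`` for
    coarse pseudo-atoms, whose scattering weight is then taken from
    ``electron_counts`` (a flat, q-independent form factor).
    """

    coords: np.ndarray
    elements: np.ndarray
    residue_index: np.ndarray
    chain_id: np.ndarray | None = None
    hydrogens: np.ndarray | None = None
    electron_counts: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        n = len(self.coords)
        if n < 1:
            raise ValueError("model needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        if self.hydrogens is None:
            self.hydrogens = np.zeros(n, dtype=int)
        self.hydrogens = np.asarray(self.hydrogens, dtype=int)
        if self.electron_counts is not None:
            self.electron_counts = np.asarray(self.electron_counts, dtype=float)
        unknown = {e for e in self.elements} - KNOWN_ELEMENTS - {"X"}
        if unknown:
            warnings.warn(f"elements outside H/C/N/O/S/P: {sorted(unknown)}")

    def __len__(self):
        return len(self.coords)

    @property
    def is_coarse(self) -> bool:
        return self.electron_counts is not None

    def total_electrons(self) -> float:
        """Electrons including implicit hydrogens (or bead counts)."""
        if self.is_coarse:
            return float(self.electron_counts.sum())
        z = np.array([ELEMENT_ELECTRONS.get(e, 0) for e in self.elements],
                     dtype=float)
        return float(z.sum() + self.hydrogens.sum())

    def electron_weights(self) -> np.ndarray:
        if self.is_coarse:
            return self.electron_counts.astype(float)
        z = np.array([ELEMENT_ELECTRONS.get(e, 0) for e in self.elements],
                     dtype=float)
        return z + self.hydrogens

    def rg(self) -> float:
        """Electron-weighted radius of gyration of the bare model, in A."""
        w = self.electron_weights()
        com = np.average(self.coords, axis=0, weights=w)
        d2 = np.sum((self.coords - com) ** 2, axis=1)
        return float(np.sqrt(np.average(d2, weights=w)))

    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0)) -> "AtomicModel":
        coords = self.coords
        if rotation is not None:
            coords = coords @ np.asarray(rotation).T
        coords = coords + np.asarray(translation, dtype=float)
        return AtomicModel(coords, self.elements, self.residue_index,
                           chain_id=self.chain_id,
                           hydrogens=self.hydrogens.copy(),
                           electron_counts=None if self.electron_counts is None
                           else self.electron_counts.copy(),
                           metadata=dict(self.metadata))


_WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}


def load_pdb(path) -> AtomicModel:
    """Load heavy atoms from a PDB file; waters and hydrogens are skipped.

    Implicit hydrogen counts are assigned from the residue templates so the
    scattering weight of each heavy-atom group includes its bound hydrogens.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("model", str(path))
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse PDB ({exc})") from exc

    coords, elements, res_idx, chains, hydros = [], [], [], [], []
    ridx = -1
    last_res = None
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip().upper()
                if resname in _WATER_RESNAMES:
                    continue
                key = (chain.id, residue.id)
                if key != last_res:
                    ridx += 1
                    last_res = key
                for atom in residue:
                    elem = (atom.element or "").strip().upper()
                    if not elem:
                        elem = atom.get_name().strip()[0].upper()
                    if elem == "H" or elem == "D":
                        continue
                    coords.append(atom.get_coord())
                    elements.append(elem)
                    res_idx.append(ridx)
                    chains.append(chain.id)
                    if resname in _SIDECHAIN_H or resname == "GLY":
                        hydros.append(implicit_hydrogens(resname, atom.get_name()))
                    else:
                        warnings.warn(f"unknown residue {resname}: H count 0 "
                                      f"for atom {atom.get_name()}")
                        hydros.append(0)
        break  # first NMR/ensemble model only
    if not coords:
        raise ParseError(f"{path}: no non-water ATOM records")
    one_letter = None
    return AtomicModel(np.array(coords, dtype=float),
                       np.array(elements, dtype=object),
                       np.array(res_idx, dtype=int),
                       chain_id=np.array(chains, dtype=object),
                       hydrogens=np.array(hydros, dtype=int),
                       metadata={"path": str(path), "sequence": one_letter})
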