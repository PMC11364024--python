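"""Per-residue constant tables for the 20 standard amino acids.

``RESIDUE_MASS_DA`` — average residue masses (amino acid minus one water).
``RESIDUE_ELECTRONS`` — electron counts of the neutral residue (heavy atoms
plus bound hydrogens, peptide-bond water loss accounted).
``RESIDUE_VOLUME_A3`` — partial residue volumes from Jacrot (1976),
Rep. Prog. Phys. 39, 911, the table conventionally used for X-ray/neutron
contrast estimates of proteins from sequence.

Chain-level sums add one water (18.015 Da, 10 electrons) for the free N/C
termini.
"""

from __future__ import annotations

from .errors import SequenceError

WATER_MASS_DA = 18.015
WATER_ELECTRONS = 10

RESIDUE_MASS_DA = {
    "G": 57.052, "A": 71.079, "S": 87.078, "P": 97.117, "V": 99.133,
    "T": 101.105, "C": 103.143, "L": 113.160, "I": 113.160, "N": 114.104,
    "D": 115.089, "Q": 128.131, "K": 128.174, "E": 129.116, "M": 131.196,
    "H": 137.141, "F": 147.177, "R": 156.188, "Y": 163.176, "W": 186.213,
}

RESIDUE_ELECTRONS = {
    "G": 30, "A": 38, "S": 46, "P": 52, "V": 54, "T": 54, "C": 54,
    "L": 62, "I": 62, "N": 60, "D": 60, "Q": 68, "K": 70, "E": 68,
    "M": 70, "H": 72, "F": 78, "R": 84, "Y": 86, "W": 98,
}

# Jacrot (1976) residue partial volumes, cubic angstroms.
RESIDUE_VOLUME_A3 = {
    "G": 66.4, "A": 91.5, "S": 99.1, "C": 105.6, "D": 113.6,
    "T": 122.1, "P": 129.3, "N": 135.2, "E": 140.6, "V": 141.7,
    "Q": 161.1, "H": 167.3, "L": 167.9, "I": 168.8, "M": 170.8,
    "K": 176.2, "R": 180.8, "F": 203.4, "Y": 203.6, "W": 237.6,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def validate_sequence(sequence: str) -> str:
    """Upper-case and validate a one-letter sequence; name the bad residue."""
    seq = sequence.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    for pos, aa in enumerate(seq, start=1):
        if aa not in RESIDUE_MASS_DA:
            raise SequenceError(f"unknown residue {aa!r} at position {pos}")
    return seq


def chain_mass(sequence: str) -> float:
    """Average molar mass (g/mol) of the peptide with free termini."""
    seq = validate_sequence(sequence)
    return sum(RESIDUE_MASS_DA[a] for a in seq) + WATER_MASS_DA


def chain_electrons(sequence: str) -> int:
    """Total electrons of the neutral peptide with free termini."""
    seq = validate_sequence(sequence)
    return sum(RESIDUE_ELECTRONS[a] for a in seq) + WATER_ELECTRONS


def chain_volume(sequence: str) -> float:
    """Jacrot (1976) sequence-summed partial volume, cubic angstroms."""
    seq = validate_sequence(sequence)
    return sum(RESIDUE_VOLUME_A3[a] for a in seq)
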