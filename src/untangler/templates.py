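"""Residue connectivity templates.

Covalent topology for the 20 standard amino acids, water, and the
"bead-peptide" residue (``BEA``) used by the synthetic fixtures.  Templates
carry connectivity only; ideal values and sigmas live in the restraint
library (:mod:`untangler.restraints`).

A bead-peptide residue is a minimal backbone analog (N, CA, C) plus a one-atom
side chain (CB).  It has enough topology to form bonds, angles and torsions
across a chain without the bookkeeping weight of real amino acids.
"""

from __future__ import annotations

MAIN_CHAIN = ("N", "CA", "C", "O", "OXT")

# heavy-atom intra-residue bonds; backbone part shared by all amino acids
_BACKBONE = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

_SIDE_CHAINS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

AMINO_ACIDS = frozenset(_SIDE_CHAINS)

RESIDUE_BONDS: dict[str, list[tuple[str, str]]] = {
    name: _BACKBONE + side for name, side in _SIDE_CHAINS.items()
}
RESIDUE_BONDS["HOH"] = [("O", "H1"), ("O", "H2")]
RESIDUE_BONDS["BEA"] = [("N", "CA"), ("CA", "C"), ("CA", "CB")]

# chain-linking bond: carbonyl C of residue i to amide N of residue i+1
PEPTIDE_LINK = ("C", "N")

# default element symbol from a PDB atom name (heavy atoms + explicit H1/H2)
def element_of(atom_name: str) -> str:
    name = atom_name.strip()
    if name.startswith(("H", "1H", "2H", "3H")):
        return "H"
    if name.startswith("S"):
        return "S"
    if name.startswith("O"):
        return "O"
    if name.startswith("N"):
        return "N"
    return "C"


def known_residue(resname: str) -> bool:
    return resname in RESIDUE_BONDS
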