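"""Shared chemical reference tables.

Residue name translation, a physicochemical similarity partition of the
20 amino acids, van-der-Waals radii, and hydrogen-bond donor/acceptor
dictionaries used by the interface module.  Kept in one flat module so the
alignment and interface layers can share them without circular imports.
"""

from __future__ import annotations

AA_3TO1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common non-standard residues mapped to their parent
    "MSE": "M", "SEC": "C", "PYL": "K",
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def three_to_one(res_name: str) -> str:
    """Map a 3-letter residue code to one letter, 'X' if unknown."""
    return AA_3TO1.get(res_name.upper(), "X")


#: Default similarity partition: aliphatic/sulfur, aromatic, basic, acidic,
#: polar, and the two conformationally special residues on their own.
#: The grouping is configurable everywhere it is consumed and is recorded in
#: output metadata, since conservation censuses depend on it.
DEFAULT_SIMILARITY_GROUPS: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AVLIMC"),
    "aromatic": frozenset("FWY"),
    "basic": frozenset("KRH"),
    "acidic": frozenset("DE"),
    "polar": frozenset("STNQ"),
    "glycine": frozenset("G"),
    "proline": frozenset("P"),
}

#: van-der-Waals radii (Å) by element, Bondi (1964) values with a protein-
#: typical carbon radius; versioned via this name.
VDW_RADII_BONDI: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "FE": 1.40, "ZN": 1.39, "MG": 1.73, "CA": 1.74,
    "NA": 2.27, "K": 2.75, "MN": 1.40, "CU": 1.40,
}

DEFAULT_VDW_RADIUS = 1.80  # fallback for elements missing from the table

# Hydrogen-bond capable heavy atoms.  Crystal structures at typical
# resolution carry no hydrogens, so donor capability is inferred from the
# residue/atom dictionary and the criterion is purely geometric.
HBOND_DONORS: dict[str, frozenset[str]] = {
    "*": frozenset({"N"}),  # backbone amide of every residue (not PRO)
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
}

HBOND_ACCEPTORS: dict[str, frozenset[str]] = {
    "*": frozenset({"O", "OXT"}),  # backbone carbonyl / C-terminal carboxylate
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "MET": frozenset({"SD"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}

#: Charged side-chain atoms for salt-bridge detection.
SALT_BRIDGE_BASIC: dict[str, frozenset[str]] = {
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

SALT_BRIDGE_ACIDIC: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}


def is_hbond_donor(res_name: str, atom_name: str) -> bool:
    if res_name == "PRO" and atom_name == "N":
        return False
    if atom_name in HBOND_DONORS["*"]:
        return True
    return atom_name in HBOND_DONORS.get(res_name, frozenset())


def is_hbond_acceptor(res_name: str, atom_name: str) -> bool:
    if atom_name in HBOND_ACCEPTORS["*"]:
        return True
    return atom_name in HBOND_ACCEPTORS.get(res_name, frozenset())
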