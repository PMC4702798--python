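"""Amino-acid heavy-atom topology and interaction typing tables.

These tables drive missing-atom detection, idealized-hydrogen H-bond
geometry (donor antecedents), hydrophobic/aromatic/ionic atom typing and
the geometric side-chain builder used by the synthetic fixtures.  Only
heavy atoms are represented; hydrogens are implicit throughout.
"""

from __future__ import annotations

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}

BACKBONE = ("N", "CA", "C", "O")

# Side-chain heavy atoms in build order (parent listed in SIDECHAIN_BONDS).
SIDECHAIN_ATOMS: dict[str, list[str]] = {
    "GLY": [],
    "ALA": ["CB"],
    "SER": ["CB", "OG"],
    "CYS": ["CB", "SG"],
    "THR": ["CB", "OG1", "CG2"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PRO": ["CB", "CG", "CD"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "HIS": ["CB", "CG", "ND1", "CE1", "NE2", "CD2"],
    "PHE": ["CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2"],
    "TYR": ["CB", "CG", "CD1", "CE1", "CZ", "CE2", "CD2", "OH"],
    "TRP": ["CB", "CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"],
}

SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "CD2"), ("CD2", "CG")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
            ("CZ", "OH")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CD2", "CE3"),
            ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
}

# Apolar heavy atoms eligible for the hydrophobic-contact bit: carbons and
# sulfurs not bonded to N/O (side chains only; backbone excluded).
APOLAR_ATOMS: dict[str, tuple[str, ...]] = {
    "GLY": (), "SER": (), "ASN": ("CB",), "ASP": ("CB",), "HIS": ("CB",),
    "ALA": ("CB",),
    "CYS": ("CB", "SG"),
    "THR": ("CG2",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "GLU": ("CB", "CG"),
    "GLN": ("CB", "CG"),
    "LYS": ("CB", "CG", "CD"),
    "ARG": ("CB", "CG"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

# Side-chain H-bond donors: heavy donor atom -> bonded heavy antecedents
# used for the idealized-hydrogen angle test.  Backbone amide N is handled
# separately (antecedents CA and preceding C).
SIDECHAIN_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "SER": {"OG": ("CB",)},
    "THR": {"OG1": ("CB",)},
    "TYR": {"OH": ("CZ",)},
    "ASN": {"ND2": ("CG",)},
    "GLN": {"NE2": ("CD",)},
    "LYS": {"NZ": ("CE",)},
    "ARG": {"NE": ("CD", "CZ"), "NH1": ("CZ",), "NH2": ("CZ",)},
    "HIS": {"ND1": ("CG", "CE1"), "NE2": ("CD2", "CE1")},
    "TRP": {"NE1": ("CD1", "CE2")},
}

# Side-chain H-bond acceptors (backbone carbonyl O handled separately).
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

# Aromatic ring atom cycles (ordered).
AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "TYR": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),),
    "HIS": (("CG", "ND1", "CE1", "NE2", "CD2"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")),
}

# Formal-charge centers at pH 7.4 (group-center convention): carboxylates
# are centred on the carboxyl carbon, guanidinium on CZ, ammonium on NZ.
CHARGE_CENTERS: dict[str, tuple[tuple[str, int], ...]] = {
    "ASP": (("CG", -1),),
    "GLU": (("CD", -1),),
    "LYS": (("NZ", +1),),
    "ARG": (("CZ", +1),),
}

ELEMENT_OF_ATOM = {"N": "N", "O": "O", "S": "S", "P": "P"}


def atom_element(atom_name: str) -> str:
    """Element symbol for a standard protein heavy-atom name."""
    return ELEMENT_OF_ATOM.get(atom_name[0], "C")


def expected_heavy_atoms(aa3: str) -> tuple[str, ...]:
    """Full expected heavy-atom complement (backbone + side chain)."""
    return BACKBONE + tuple(SIDECHAIN_ATOMS.get(aa3, []))


# Van der Waals radii (Bondi) used by the Shrake-Rupley ASA engine.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.20,
             "MG": 1.73, "ZN": 1.39, "MN": 1.73, "NA": 2.27, "K": 2.75,
             "CA": 2.31, "FE": 1.63}


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), 1.70)
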