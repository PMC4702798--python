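"""Minimal Tripos MOL2 writing.

MOL2 is the exchange format for processed entities (protein, pocket,
ligands, waters, probe sets).  Only the MOLECULE/ATOM/BOND records are
emitted; SYBYL atom types are assigned from element and aromaticity,
which is sufficient for downstream readers (e.g. RDKit) to recover the
topology.
"""

from __future__ import annotations

from rdkit import Chem

from .model import Monomer

_SYBYL = {"C": "C.3", "N": "N.3", "O": "O.3", "S": "S.3", "P": "P.3",
          "H": "H", "F": "F", "CL": "Cl", "BR": "Br", "I": "I",
          "MG": "Mg", "ZN": "Zn", "MN": "Mn", "NA": "Na", "K": "K",
          "CA": "Ca", "FE": "Fe"}

_BOND_TYPE = {Chem.BondType.SINGLE: "1", Chem.BondType.DOUBLE: "2",
              Chem.BondType.TRIPLE: "3", Chem.BondType.AROMATIC: "ar"}


def _sybyl(element: str, aromatic: bool = False) -> str:
    e = element.upper()
    if aromatic and e in ("C", "N"):
        return f"{element.capitalize()}.ar"
    return _SYBYL.get(e, element.capitalize())


def mol_to_mol2(mol: Chem.Mol, name: str = "ligand",
                atom_names: tuple[str, ...] = ()) -> str:
    """Serialize an RDKit mol (with one conformer) to MOL2."""
    conf = mol.GetConformer()
    n_at, n_bd = mol.GetNumAtoms(), mol.GetNumBonds()
    lines = ["@<TRIPOS>MOLECULE", name, f"{n_at} {n_bd} 1 0 0", "SMALL",
             "USER_CHARGES", "", "@<TRIPOS>ATOM"]
    for a in mol.GetAtoms():
        i = a.GetIdx()
        p = conf.GetAtomPosition(i)
        nm = atom_names[i] if i < len(atom_names) else f"{a.GetSymbol()}{i + 1}"
        lines.append(f"{i + 1:>7} {nm:<8} {p.x:>9.4f} {p.y:>9.4f} {p.z:>9.4f} "
                     f"{_sybyl(a.GetSymbol(), a.GetIsAromatic()):<7} 1 LIG "
                     f"{float(a.GetFormalCharge()):>8.4f}")
    lines.append("@<TRIPOS>BOND")
    for j, b in enumerate(mol.GetBonds()):
        lines.append(f"{j + 1:>6} {b.GetBeginAtomIdx() + 1:>5} "
                     f"{b.GetEndAtomIdx() + 1:>5} {_BOND_TYPE.get(b.GetBondType(), '1'):>4}")
    return "\n".join(lines) + "\n"


def monomer_to_mol2(monomer: Monomer, name: str | None = None,
                    include_hetero: bool = False) -> str:
    """Serialize a protein monomer to MOL2 (no bond records between
    residues are inferred; a sequential backbone bond list is emitted)."""
    atoms = []
    for res in monomer.residues:
        for a in res.atoms:
            atoms.append((a, res.name, res.seqid))
    if include_hetero:
        for h in monomer.hetero_groups:
            for a in h.atoms:
                atoms.append((a, h.comp_id, h.seqid))
    lines = ["@<TRIPOS>MOLECULE", name or monomer.source_id,
             f"{len(atoms)} 0 1 0 0", "PROTEIN", "NO_CHARGES", "",
             "@<TRIPOS>ATOM"]
    for i, (a, rname, rid) in enumerate(atoms):
        lines.append(f"{i + 1:>7} {a.name:<8} {a.pos[0]:>9.4f} {a.pos[1]:>9.4f} "
                     f"{a.pos[2]:>9.4f} {_sybyl(a.element):<7} {rid} {rname}{rid} 0.0000")
    lines.append("@<TRIPOS>BOND")
    return "\n".join(lines) + "\n"


def points_to_mol2(points, name: str = "probes") -> str:
    """Point cloud (probe sets, water centroids) as pseudo-atom MOL2."""
    pts = list(points)
    lines = ["@<TRIPOS>MOLECULE", name, f"{len(pts)} 0 1 0 0", "SMALL",
             "NO_CHARGES", "", "@<TRIPOS>ATOM"]
    for i, p in enumerate(pts):
        lines.append(f"{i + 1:>7} DU{i + 1:<5} {p[0]:>9.4f} {p[1]:>9.4f} "
                     f"{p[2]:>9.4f} {'Du':<7} 1 PRB 0.0000")
    lines.append("@<TRIPOS>BOND")
    return "\n".join(lines) + "\n"
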