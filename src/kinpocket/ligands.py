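"""Ligand chemical topology: curation, protonation and interaction typing.

Hetero groups extracted from structure files carry only elements and
coordinates; bond orders and charges must be restored before H-bond and
ionic interactions can be typed reliably.  When the chemical-component
dictionary has an entry for the component code, its bond orders and
formal charges are authoritative (matched by atom name); otherwise bonds
are perceived from geometry.  Protonation states are then assigned by
rule at physiological pH: carboxylates and acidic phosphate oxygens are
deprotonated, aliphatic amines and amidine/guanidine groups protonated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDetermineBonds
from rdkit.Geometry import Point3D

from .errors import InputError
from .model import HeteroGroup

_BOND_ORDER = {
    "SING": Chem.BondType.SINGLE, "DOUB": Chem.BondType.DOUBLE,
    "TRIP": Chem.BondType.TRIPLE, "AROM": Chem.BondType.AROMATIC,
    "1": Chem.BondType.SINGLE, "2": Chem.BondType.DOUBLE,
    "3": Chem.BondType.TRIPLE, "AR": Chem.BondType.AROMATIC,
}

# pH 7.4 protonation rules as (SMARTS, atom position in match, new charge).
_PROTONATION_RULES: tuple[tuple[str, int, int], ...] = (
    ("[CX3](=O)[OX2H1]", 2, -1),                  # carboxylic acid -> carboxylate
    ("[OX2H1][PX4]", 0, -1),                      # acidic phosphate oxygen
    ("[NX3;H2;!$(NC=O);!$(N[a]);!$(N=*);!$(N[O,N])]", 0, +1),   # primary aliphatic amine
    ("[NX3;H1;!R;!$(NC=O);!$(N[a]);!$(N=*);!$(N[O,N])]([CX4])[CX4]", 0, +1),  # secondary amine
    ("[NX2;!$(N[O,N])]=[CX3]([NX3])", 0, +1),     # amidine / guanidine imine N
)


@dataclass
class LigandRecord:
    """A curated small molecule: RDKit mol (heavy atoms, one 3D conformer)
    plus provenance flags."""

    component_id: str
    mol: Chem.Mol
    protonation_applied: bool = True
    curation_changed: bool = False
    from_dictionary: bool = False
    atom_names: tuple[str, ...] = ()

    def coords(self) -> np.ndarray:
        conf = self.mol.GetConformer()
        return np.array([list(conf.GetAtomPosition(i))
                         for i in range(self.mol.GetNumAtoms())])

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1)

    # ---- interaction typing (heavy-atom indices) ----

    def apolar_atoms(self) -> list[int]:
        """Carbons with no N/O/F neighbour, plus sulfurs."""
        out = []
        for a in self.mol.GetAtoms():
            if a.GetSymbol() == "S":
                out.append(a.GetIdx())
            elif a.GetSymbol() == "C":
                if not any(n.GetSymbol() in ("N", "O", "F") for n in a.GetNeighbors()):
                    out.append(a.GetIdx())
        return out

    def aromatic_rings(self) -> list[tuple[int, ...]]:
        info = self.mol.GetRingInfo()
        rings = []
        for ring in info.AtomRings():
            if all(self.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
                rings.append(tuple(ring))
        return rings

    def donor_atoms(self) -> list[tuple[int, tuple[int, ...]]]:
        """(donor index, heavy antecedent indices) for N/O bearing >= 1 H."""
        out = []
        for a in self.mol.GetAtoms():
            if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() >= 1:
                ante = tuple(n.GetIdx() for n in a.GetNeighbors()
                             if n.GetAtomicNum() > 1)
                out.append((a.GetIdx(), ante))
        return out

    def acceptor_atoms(self) -> list[int]:
        out = []
        for a in self.mol.GetAtoms():
            if a.GetFormalCharge() > 0:
                continue
            if a.GetSymbol() == "O":
                out.append(a.GetIdx())
            elif a.GetSymbol() == "N" and a.GetTotalNumHs() == 0:
                out.append(a.GetIdx())
        return out

    def charge_centers(self) -> list[tuple[np.ndarray, int]]:
        """(position, sign) per charged group, group-centre convention:
        carboxylate/phosphate centred on the C/P, ammonium/guanidinium on
        the charged N / central C."""
        coords = self.coords()
        out = []
        seen_centers: set[int] = set()
        for a in self.mol.GetAtoms():
            q = a.GetFormalCharge()
            if q == 0:
                continue
            center = a.GetIdx()
            if q < 0 and a.GetSymbol() == "O":
                for n in a.GetNeighbors():
                    if n.GetSymbol() in ("C", "P", "S"):
                        center = n.GetIdx()
                        break
            if q > 0 and a.GetSymbol() == "N":
                for n in a.GetNeighbors():
                    if n.GetSymbol() == "C" and sum(
                            1 for m in n.GetNeighbors() if m.GetSymbol() == "N") >= 2:
                        center = n.GetIdx()   # guanidinium / amidinium carbon
                        break
            if center in seen_centers:
                continue
            seen_centers.add(center)
            out.append((coords[center], 1 if q > 0 else -1))
        return out


def _mol_from_group(group: HeteroGroup) -> tuple[Chem.RWMol, list[str]]:
    mol = Chem.RWMol()
    conf = Chem.Conformer(len([a for a in group.atoms if a.element.upper() != "H"]))
    names = []
    i = 0
    for a in group.atoms:
        if a.element.upper() == "H":
            continue
        at = Chem.Atom(a.element.capitalize())
        at.SetNoImplicit(True)
        mol.AddAtom(at)
        conf.SetAtomPosition(i, Point3D(*map(float, a.pos)))
        names.append(a.name)
        i += 1
    mol.AddConformer(conf)
    return mol, names


def _apply_dictionary(mol: Chem.RWMol, names: list[str], block) -> bool:
    """Set bonds/charges from a chemical-component-dictionary block;
    returns False on atom-name mismatch."""
    dict_atoms = {}
    for row in block.find("_chem_comp_atom.", ["atom_id", "type_symbol", "charge"]):
        charge = row[2]
        dict_atoms[row.str(0)] = (row.str(1),
                                  int(charge) if charge not in ("?", ".") else 0)
    if not dict_atoms:
        return False
    index_of = {}
    for i, nm in enumerate(names):
        if nm not in dict_atoms:
            if mol.GetAtomWithIdx(i).GetSymbol().upper() != "H":
                return False
            continue
        index_of[nm] = i
        mol.GetAtomWithIdx(i).SetFormalCharge(dict_atoms[nm][1])
    bonds = block.find("_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_order"])
    for row in bonds:
        a, b = row.str(0), row.str(1)
        if a in index_of and b in index_of:
            order = _BOND_ORDER.get(row.str(2).upper(), Chem.BondType.SINGLE)
            mol.AddBond(index_of[a], index_of[b], order)
    return True


def _perceive_bonds(mol: Chem.RWMol) -> None:
    for a in mol.GetAtoms():
        a.SetNoImplicit(False)
    try:
        rdDetermineBonds.DetermineBonds(mol, charge=0)
    except Exception:
        try:
            rdDetermineBonds.DetermineConnectivity(mol)
        except Exception as exc:      # pragma: no cover - degenerate input
            raise InputError(f"bond perception failed: {exc}") from exc


def _sanitize(mol: Chem.Mol) -> None:
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                         | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
                         | Chem.SanitizeFlags.SANITIZE_SYMMRINGS,
                         catchErrors=True)


def protonate_ph74(mol: Chem.Mol) -> bool:
    """Rule-based protonation at physiological pH; idempotent.  Returns
    True when any charge was changed."""
    changed = False
    for smarts, pos, charge in _PROTONATION_RULES:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            atom = mol.GetAtomWithIdx(match[pos])
            if atom.GetFormalCharge() == charge:
                continue
            atom.SetFormalCharge(charge)
            if charge < 0 and atom.GetTotalNumHs() > 0:
                atom.SetNumExplicitHs(0)
                atom.SetNoImplicit(True)
            changed = True
    if changed:
        mol.UpdatePropertyCache(strict=False)
        _sanitize(mol)
    return changed


def curate_ligand_topology(group: HeteroGroup, dictionary=None,
                           water_components: tuple[str, ...] = ("HOH", "DOD", "WAT"),
                           ) -> LigandRecord:
    """Build a curated :class:`LigandRecord` from a hetero group.

    ``dictionary`` is a ``gemmi.cif.Document`` of chemical components; when
    it holds a block for the component code, its topology is used (matched
    by atom name), otherwise bonds are perceived from geometry.
    """
    if group.comp_id.upper() in water_components:
        raise InputError("water is not a ligand (route to waters)")
    if group.n_heavy < 1:
        raise InputError("hetero group has no heavy atoms")
    mol, names = _mol_from_group(group)
    from_dict = False
    if dictionary is not None:
        block = None
        for b in dictionary:
            if b.name.upper().removeprefix("COMP_") == group.comp_id.upper():
                block = b
                break
        if block is not None:
            before = Chem.RWMol(mol)
            if _apply_dictionary(mol, names, block):
                from_dict = True
            else:
                warnings.warn(
                    f"atom-name mismatch against dictionary entry "
                    f"{group.comp_id}; falling back to geometric perception")
                mol = before
    if not from_dict:
        _perceive_bonds(mol)
    for a in mol.GetAtoms():
        a.SetNoImplicit(False)
    mol.UpdatePropertyCache(strict=False)
    _sanitize(mol)
    pre = Chem.MolToSmiles(Chem.Mol(mol)) if mol.GetNumAtoms() else ""
    changed = protonate_ph74(mol)
    post_mol = mol.GetMol()
    _sanitize(post_mol)
    return LigandRecord(component_id=group.comp_id, mol=post_mol,
                        protonation_applied=True,
                        curation_changed=changed or not from_dict,
                        from_dictionary=from_dict, atom_names=tuple(names))


def record_from_mol(comp_id: str, mol: Chem.Mol,
                    atom_names: tuple[str, ...] = ()) -> LigandRecord:
    """Wrap an already-built RDKit mol (fixture path) applying the same
    protonation rules."""
    mol = Chem.Mol(mol)
    _sanitize(mol)
    changed = protonate_ph74(mol)
    return LigandRecord(component_id=comp_id, mol=mol, protonation_applied=True,
                        curation_changed=changed, from_dictionary=False,
                        atom_names=atom_names or tuple(
                            f"{a.GetSymbol()}{a.GetIdx()+1}" for a in mol.GetAtoms()))
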