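"""Synthetic kinase-ligand complexes with known ground truth.

Every pipeline stage is testable without downloads: complexes are grown
on the geometric master scaffold with *designed* protein-ligand contacts
(each contact placed analytically to satisfy one interaction rule with
margin), known gaps, mutations, conformation classes, waters and decoy
entities.  The generator writes standard files (PDB, SDF, MOL2, a
chemical-component dictionary, a JSON manifest) so the file-parsing path
is exercised end to end.

Fixture ligands are topological molecules whose fragments are placed
geometrically; bond lengths between fragments are not physical.  Scaffold
realism is explicitly not a goal — ground truth and reproducibility are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from .config import DEFAULT_CONFIG
from .errors import FixtureSpecError
from .geometry import random_rotation, unit
from .ligands import LigandRecord, record_from_mol
from .model import Atom, HeteroGroup, Monomer
from .mol2 import mol_to_mol2, monomer_to_mol2
from .pocket_mapping import master_pocket_sequence
from .scaffold import DFG_CLASSES, build_domain, pocket_of_domain

# ---------------------------------------------------------------------------
# Ground-truth geometry in the master frame

# Conserved water sites (master frame).  O1/O2 sit in the back cleft and
# are populated only by DFG-out structures.
TRUE_WATER_SITES: dict[str, tuple[float, float, float]] = {
    "I1": (6.3, -1.0, 1.8), "I2": (1.2, -4.8, 3.8), "I3": (0.2, -0.5, 4.6),
    "I4": (-1.5, -4.0, -1.0), "I5": (-1.8, 1.8, -0.5), "I6": (2.0, 2.2, 3.2),
    "I7": (5.0, 2.5, -1.5), "I8": (1.0, -5.5, -2.0), "I9": (0.0, 3.5, -3.2),
    "I10": (6.0, 4.5, 0.5), "I11": (6.8, 2.2, 3.4),
    "O1": (-8.8, -7.5, -3.5), "O2": (-7.2, -0.5, -1.8),
}
DFG_OUT_SITES = ("O1", "O2")

# Major binding-site regions as axis-aligned boxes and the twelve
# subpockets as spheres (center, radius), all in the master frame.
MAJOR_BOXES: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "front_cleft": ((1.5, -6.5, -4.5), (8.0, 6.0, 5.0)),
    "gate_area": ((-2.5, -7.0, -4.5), (1.5, 5.0, 5.0)),
    "back_cleft": ((-9.5, -8.0, -5.0), (-2.5, 6.5, 4.0)),
}
SUBPOCKET_SPHERES: dict[str, tuple[tuple[float, float, float], float]] = {
    "FP-I": ((5.5, -1.0, 0.5), 1.6), "FP-II": ((3.0, 3.5, 2.5), 1.6),
    "BP-I-A": ((0.0, -4.5, 2.5), 1.4), "BP-I-B": ((-1.0, -2.0, -0.5), 1.4),
    "BP-II-in": ((-4.5, -1.0, 1.5), 1.3), "BP-II-A-in": ((-5.8, -4.2, 2.6), 1.2),
    "BP-II-B-in": ((-5.8, 2.2, 2.8), 1.2), "BP-II-out": ((-7.5, -1.0, 0.0), 1.3),
    "BP-II-B": ((-7.0, 3.5, -0.5), 1.2), "BP-III": ((-7.0, -5.5, -1.5), 1.3),
    "BP-IV": ((-5.5, 5.0, -3.2), 1.3), "BP-V": ((-7.5, 0.5, -3.5), 1.3),
}
SUB_TO_MAJOR = {name: ("front_cleft" if name.startswith("FP") else
                       "gate_area" if name.startswith("BP-I-") else "back_cleft")
                for name in SUBPOCKET_SPHERES}

_APPROACH_POINTS = {"hinge": (1.5, 0.0, 0.3), "linker": (2.0, 2.0, 0.0),
                    "GK": (0.5, -0.5, 0.5), "xDFG": (0.0, -2.0, 1.0),
                    "g.l": (0.0, -2.0, 0.0)}


def subpocket_labels_for(coords: np.ndarray) -> set[str]:
    """Geometric ground-truth labels for a ligand atom cloud."""
    labels: set[str] = set()
    for name, ((x0, y0, z0), (x1, y1, z1)) in MAJOR_BOXES.items():
        inside = ((coords[:, 0] >= x0) & (coords[:, 0] <= x1)
                  & (coords[:, 1] >= y0) & (coords[:, 1] <= y1)
                  & (coords[:, 2] >= z0) & (coords[:, 2] <= z1))
        if inside.any():
            labels.add(name)
    for name, (center, radius) in SUBPOCKET_SPHERES.items():
        if (np.linalg.norm(coords - np.asarray(center), axis=1) <= radius).any():
            labels.add(name)
    return labels


# ---------------------------------------------------------------------------
# Specifications

@dataclass(frozen=True)
class DesignedContact:
    """One designed protein-ligand interaction at a pocket slot."""

    slot: int
    interaction: str         # one of fingerprint.INTERACTION_TYPES


@dataclass
class FixtureSpec:
    """Recipe for one synthetic complex."""

    seed: int = 0
    source_id: str = "fixture"
    pocket_substitutions: dict[int, str] = field(default_factory=dict)
    inward_slots: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    dfg: str = "in"
    alpha_c_distance: float | None = None
    gloop_lift: float = 0.0
    contacts: tuple[DesignedContact, ...] = ()
    gap_slots: tuple[int, ...] = ()
    truncate_atoms: dict[int, tuple[str, ...]] = field(default_factory=dict)
    noise_sigma: float = 0.0
    rigid_jumble: bool = False
    occupy_subpockets: tuple[str, ...] = ()   # inert atoms at sphere centers
    waters: tuple[str, ...] = ()          # water-site labels
    off_cluster_waters: tuple[tuple[float, float, float], ...] = ()
    extras: tuple[str, ...] = ()          # subset of {"ion","cofactor","allosteric"}
    ligand_component: str = "LIG"


@dataclass
class FixtureComplex:
    """A generated complex plus its ground-truth manifest."""

    spec: FixtureSpec
    monomer: Monomer                 # protein + hetero groups, final coords
    ligand: LigandRecord | None
    manifest: dict

    def dictionary(self):
        """In-memory chemical-component dictionary for this complex's
        ligand; fixture ligands need their explicit topology (their
        fragment geometry defeats bond perception by distance)."""
        if self.ligand is None:
            return None
        return gemmi.cif.read_string(ccd_text([self.ligand]))


# ---------------------------------------------------------------------------
# Ligand fragment recipes

_IMPLIED_BITS = {
    "hydrophobic": ("hydrophobic",),
    "aromatic_f2f": ("aromatic_f2f", "hydrophobic"),
    "aromatic_e2f": ("aromatic_e2f", "hydrophobic"),
    "hbond_donor": ("hbond_donor",),
    "hbond_acceptor": ("hbond_acceptor",),
    "ionic_positive": ("ionic_positive",),
    "ionic_negative": ("ionic_negative",),
}


class _LigandBuilder:
    def __init__(self):
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[int, int, Chem.BondType]] = []
        self.stems: list[int] = []

    def add(self, element: str, pos) -> int:
        self.elements.append(element)
        self.coords.append(np.asarray(pos, float))
        return len(self.elements) - 1

    def add_stem(self, pos, direction) -> int:
        """Linker attachment carbon carrying a fluorine so that it is inert
        under every interaction rule (not apolar, not donor/acceptor)."""
        stem = self.add("C", pos)
        v = unit(np.asarray(direction, float))
        w = unit(np.cross(v, [0.0, 0.0, 1.0]) if abs(v[2]) < 0.9
                 else np.cross(v, [1.0, 0.0, 0.0]))
        f = self.add("F", np.asarray(pos, float) + 1.35 * w)
        self.bond(stem, f)
        self.stems.append(stem)
        return stem

    def bond(self, i: int, j: int, order=Chem.BondType.SINGLE):
        self.bonds.append((i, j, order))

    def merge(self, other: "_LigandBuilder") -> None:
        offset = len(self.elements)
        self.elements.extend(other.elements)
        self.coords.extend(other.coords)
        self.bonds.extend((i + offset, j + offset, o) for i, j, o in other.bonds)
        self.stems.extend(s + offset for s in other.stems)

    def to_mol(self) -> tuple[Chem.Mol, tuple[str, ...]]:
        mol = Chem.RWMol()
        conf = Chem.Conformer(len(self.elements))
        counters: dict[str, int] = {}
        names = []
        for i, (el, xyz) in enumerate(zip(self.elements, self.coords)):
            mol.AddAtom(Chem.Atom(el))
            conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
            counters[el] = counters.get(el, 0) + 1
            names.append(f"{el}{counters[el]}")
        for s in range(len(self.stems) - 1):
            self.bonds.append((self.stems[s], self.stems[s + 1],
                               Chem.BondType.SINGLE))
        for i, j, order in self.bonds:
            if mol.GetBondBetweenAtoms(i, j) is None:
                mol.AddBond(i, j, order)
        mol.AddConformer(conf)
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return m, tuple(names)


def _residue_tip_direction(residue, names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    ca = residue.coord("CA")
    tips = [(residue.coord(n), np.linalg.norm(residue.coord(n) - ca))
            for n in names if residue.has_atom(n)]
    if not tips:
        raise FixtureSpecError(f"residue {residue.name} lacks anchor atoms {names}")
    tip = max(tips, key=lambda t: t[1])[0]
    return tip, unit(tip - ca)


def _ring_frame(residue) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from .residues import AROMATIC_RINGS
    cycle = AROMATIC_RINGS[residue.name][0]
    coords = np.array([residue.coord(a) for a in cycle])
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2], unit(coords[0] - centroid)


# contact kinds whose recipe addresses the side chain (the residue is
# grown pointing into the cavity for these)
_SIDECHAIN_KINDS = ("hydrophobic", "aromatic_f2f", "aromatic_e2f",
                    "ionic_positive", "ionic_negative")


def _hbond_candidates(contact: DesignedContact, residue, region: str) -> list[np.ndarray]:
    """Candidate approach directions for the H-bond recipes; the generator
    keeps the first one whose realized bits match the design."""
    approach = np.asarray(_APPROACH_POINTS.get(region, (0.5, 0.0, 0.5)), float)
    if contact.interaction == "hbond_donor":
        origin = residue.coord("N")
        hdir = unit(origin - residue.coord("CA"))
    else:
        origin = residue.coord("O")
        c = residue.coord("C")
        hdir = unit(origin - c) if c is not None else np.array([0.0, 0.0, 1.0])
    base = unit(approach - origin)
    cands = [base, hdir, unit(base + hdir), unit(base + 0.3 * hdir)]
    return cands


def _place_fragment(contact: DesignedContact, residue, region: str,
                    builder: _LigandBuilder,
                    protein_coords: np.ndarray,
                    direction: np.ndarray | None = None) -> None:
    kind = contact.interaction
    approach = np.asarray(_APPROACH_POINTS.get(region, (0.5, 0.0, 0.5)), float)
    if kind == "hbond_donor":
        # protein backbone N donates to a ligand carbonyl oxygen
        n = residue.coord("N")
        if n is None or residue.name == "PRO":
            raise FixtureSpecError(f"slot {contact.slot}: no amide donor")
        v = unit(approach - n) if direction is None else unit(direction)
        o = builder.add("O", n + 2.9 * v)
        c = builder.add("C", n + (2.9 + 1.23) * v)
        builder.bond(o, c, Chem.BondType.DOUBLE)
        stem = builder.add_stem(n + (2.9 + 1.23 + 1.45) * v, v)
        builder.bond(c, stem)
    elif kind == "hbond_acceptor":
        # ligand amide N-H donates to the protein backbone carbonyl
        o = residue.coord("O")
        if o is None:
            raise FixtureSpecError(f"slot {contact.slot}: no backbone O")
        v = unit(approach - o) if direction is None else unit(direction)
        nn = builder.add("N", o + 2.9 * v)
        c1 = builder.add("C", o + (2.9 + 1.38) * v)
        w = unit(np.cross(v, [0.0, 0.0, 1.0]) if abs(v[2]) < 0.9
                 else np.cross(v, [1.0, 0.0, 0.0]))
        oc = builder.add("O", o + (2.9 + 1.38) * v + 1.23 * w)
        builder.bond(nn, c1)
        builder.bond(c1, oc, Chem.BondType.DOUBLE)
        stem = builder.add_stem(o + (2.9 + 1.38 + 1.5) * v, v)
        builder.bond(c1, stem)
    elif kind == "hydrophobic":
        from .residues import APOLAR_ATOMS
        tip, v = _residue_tip_direction(residue, APOLAR_ATOMS.get(residue.name, ()))
        c = builder.add("C", tip + 4.0 * v)
        stem = builder.add_stem(tip + 5.5 * v, v)
        builder.bond(c, stem)
    elif kind in ("aromatic_f2f", "aromatic_e2f"):
        if residue.name not in ("PHE", "TYR", "HIS", "TRP"):
            raise FixtureSpecError(
                f"slot {contact.slot}: {residue.name} has no aromatic ring "
                "(substitute the slot to F/Y first)")
        centroid, normal, in_plane = _ring_frame(residue)
        dist = 3.6 if kind == "aromatic_f2f" else 4.3
        # choose the normal side with more clearance from the protein
        clear = []
        for side in (normal, -normal):
            p = centroid + dist * side
            clear.append(np.sqrt(((protein_coords - p) ** 2).sum(1)).min())
        side = normal if clear[0] >= clear[1] else -normal
        ring_center = centroid + dist * side
        if kind == "aromatic_f2f":
            d1, d2 = in_plane, unit(np.cross(side, in_plane))
        else:
            d1, d2 = side, in_plane       # ring plane contains the normal
        idx = []
        for k in range(6):
            th = np.radians(60 * k)
            idx.append(builder.add(
                "C", ring_center + 1.39 * (np.cos(th) * d1 + np.sin(th) * d2)))
        for k in range(6):
            builder.bond(idx[k], idx[(k + 1) % 6], Chem.BondType.AROMATIC)
        builder.stems.append(idx[0])
    elif kind == "ionic_positive":
        # protein Lys/Arg cation vs a ligand carboxylate
        anchor = {"LYS": "NZ", "ARG": "CZ"}.get(residue.name)
        if anchor is None or not residue.has_atom(anchor):
            raise FixtureSpecError(
                f"slot {contact.slot}: needs K/R side chain for ionic_positive")
        tip, v = _residue_tip_direction(residue, (anchor,))
        cc = tip + 4.0 * v
        w = unit(np.cross(v, [0.0, 0.0, 1.0]) if abs(v[2]) < 0.9
                 else np.cross(v, [1.0, 0.0, 0.0]))
        c = builder.add("C", cc)
        o1 = builder.add("O", cc + 1.26 * unit(0.3 * v + 0.95 * w))
        o2 = builder.add("O", cc + 1.26 * unit(0.3 * v - 0.95 * w))
        builder.bond(c, o1, Chem.BondType.DOUBLE)
        builder.bond(c, o2)     # O-H; deprotonated by the pH 7.4 rules
        stem = builder.add_stem(cc + 1.5 * v, v)
        builder.bond(c, stem)
    elif kind == "ionic_negative":
        # protein Asp/Glu carboxylate vs a ligand primary ammonium
        anchor = {"ASP": "CG", "GLU": "CD"}.get(residue.name)
        if anchor is None or not residue.has_atom(anchor):
            raise FixtureSpecError(
                f"slot {contact.slot}: needs D/E side chain for ionic_negative")
        cg = residue.coord(anchor)
        od = [residue.coord(n) for n in ("OD1", "OD2", "OE1", "OE2")
              if residue.has_atom(n)]
        w = unit(np.cross(od[0] - cg, od[1] - cg))
        if np.linalg.norm(cg + 4.0 * w) > np.linalg.norm(cg - 4.0 * w):
            w = -w                      # approach from the cavity side
        nn = builder.add("N", cg + 4.0 * w)
        stem = builder.add_stem(cg + 5.5 * w, w)
        builder.bond(nn, stem)
    else:
        raise FixtureSpecError(f"unknown interaction kind {kind!r}")


def _realize_fragment(contact: DesignedContact, residue, region: str,
                      protein_coords: np.ndarray, pocket) -> _LigandBuilder:
    """Place one fragment, trying candidate approach directions for the
    H-bond recipes; the accepted candidate must realize exactly the
    designed bits (hydrophobic-only extras tolerated)."""
    from .fingerprint import INTERACTION_TYPES, compute_ifp

    designed = {(contact.slot, t) for t in _IMPLIED_BITS[contact.interaction]}
    if contact.interaction in ("hbond_donor", "hbond_acceptor"):
        candidates = _hbond_candidates(contact, residue, region)
    else:
        candidates = [None]
    failures = []
    for cand in candidates:
        b = _LigandBuilder()
        _place_fragment(contact, residue, region, b, protein_coords,
                        direction=cand)
        mol, names = b.to_mol()
        rec = record_from_mol("FRG", mol, atom_names=names)
        fp = compute_ifp(pocket, rec)
        realized = {(i // 7 + 1, INTERACTION_TYPES[i % 7]) for i in fp.on_bits()}
        extras = realized - designed
        if designed <= realized and all(t == "hydrophobic" for _, t in extras):
            return b
        failures.append(sorted(realized ^ designed))
    raise FixtureSpecError(
        f"contact {contact.interaction}@{contact.slot} cannot be realized "
        f"cleanly at this slot (bit mismatches per candidate: {failures})")


# ---------------------------------------------------------------------------
# Complex generation

def _expected_class_alpha_c(distance: float | None) -> str:
    cfg = DEFAULT_CONFIG.conformation
    if distance is None:
        return "aC-in"
    if distance <= cfg.alpha_c_in_max:
        return "aC-in"
    if distance <= cfg.alpha_c_outlike_max:
        return "aC-outlike"
    return "aC-out"


def generate_complex(spec: FixtureSpec) -> FixtureComplex:
    """Build a synthetic complex; deterministic for a fixed spec."""
    from .fingerprint import INTERACTION_TYPES, compute_ifp

    if spec.dfg not in DFG_CLASSES:
        raise FixtureSpecError(f"unknown DFG class {spec.dfg!r}")
    if spec.noise_sigma < 0:
        raise FixtureSpecError("noise sigma must be >= 0")
    seen = set()
    for c in spec.contacts:
        key = (c.slot, c.interaction)
        if key in seen:
            raise FixtureSpecError(f"duplicate contact {key}")
        seen.add(key)

    rng = np.random.default_rng(spec.seed)
    inward = dict(spec.inward_slots)
    for c in spec.contacts:
        if c.interaction in _SIDECHAIN_KINDS:
            inward.setdefault(c.slot, (0.0, 0.0, 0.0))
    monomer = build_domain(
        pocket_substitutions=spec.pocket_substitutions, dfg=spec.dfg,
        alpha_c_distance=spec.alpha_c_distance, gloop_lift=spec.gloop_lift,
        delete_slots=tuple(spec.gap_slots),
        truncate_atoms=spec.truncate_atoms, inward_slots=inward,
        source_id=spec.source_id)
    pocket = pocket_of_domain(monomer)

    ligand = None
    atom_names: tuple[str, ...] = ()
    expected_bits: list[tuple[int, str]] = []
    incidental_bits: list[tuple[int, str]] = []
    if spec.contacts or spec.occupy_subpockets:
        table_region = {s.index: s.region for s in pocket.slots}
        protein_coords = monomer.protein_coords()
        builder = _LigandBuilder()
        for contact in spec.contacts:
            slot = pocket.slot(contact.slot)
            if slot.is_gap:
                raise FixtureSpecError(f"contact slot {contact.slot} is gapped")
            fragment = _realize_fragment(contact, slot.residue,
                                         table_region[contact.slot],
                                         protein_coords, pocket)
            builder.merge(fragment)
            expected_bits.extend((contact.slot, b)
                                 for b in _IMPLIED_BITS[contact.interaction])
        for label in spec.occupy_subpockets:
            if label not in SUBPOCKET_SPHERES:
                raise FixtureSpecError(f"unknown subpocket {label!r}")
            center, _ = SUBPOCKET_SPHERES[label]
            builder.add_stem(np.asarray(center, float), (1.0, 0.0, 0.0))
        mol, atom_names = builder.to_mol()
        ligand = record_from_mol(spec.ligand_component, mol,
                                 atom_names=atom_names)
        # construction-time verification against the in-memory rule engine:
        # every designed bit must realize; extra bits are tolerated only if
        # they are incidental hydrophobic packing, and are recorded.
        fp = compute_ifp(pocket, ligand)
        designed = {(s, t) for s, t in expected_bits}
        realized = {(i // 7 + 1, INTERACTION_TYPES[i % 7]) for i in fp.on_bits()}
        extras_ = realized - designed
        if designed - realized or any(t != "hydrophobic" for _, t in extras_):
            raise FixtureSpecError(
                f"designed contacts not realized cleanly: "
                f"unexpected={sorted(realized - designed)} "
                f"missing={sorted(designed - realized)}")
        incidental_bits = sorted(extras_)

    # hetero groups: ligand, waters, decoys
    hetero: list[HeteroGroup] = []
    het_seqid = 501
    if ligand is not None:
        atoms = [Atom(nm, el, xyz) for nm, el, xyz in
                 zip(atom_names, [a.GetSymbol() for a in ligand.mol.GetAtoms()],
                     ligand.coords())]
        hetero.append(HeteroGroup(spec.ligand_component, het_seqid,
                                  monomer.chain_id, atoms))
        het_seqid += 1
    water_positions = []
    for label in spec.waters:
        if label not in TRUE_WATER_SITES:
            raise FixtureSpecError(f"unknown water site {label!r}")
        water_positions.append(np.asarray(TRUE_WATER_SITES[label], float))
    water_positions.extend(np.asarray(p, float) for p in spec.off_cluster_waters)
    for pos in water_positions:
        hetero.append(HeteroGroup("HOH", het_seqid, monomer.chain_id,
                                  [Atom("O", "O", pos)]))
        het_seqid += 1
    if "ion" in spec.extras:
        hetero.append(HeteroGroup("MG", het_seqid, monomer.chain_id,
                                  [Atom("MG", "MG", np.array([12.0, 18.0, 6.0]))]))
        het_seqid += 1
    if "cofactor" in spec.extras:
        base = np.array([6.0, 40.0, -6.0])
        atoms = [Atom(n, e, base + off) for n, e, off in
                 [("PA", "P", (0.0, 0.0, 0.0)), ("O1A", "O", (1.5, 0.0, 0.0)),
                  ("O2A", "O", (-0.8, 1.3, 0.0)), ("C5'", "C", (0.0, -1.6, 0.8))]]
        hetero.append(HeteroGroup("ATP", het_seqid, monomer.chain_id, atoms))
        het_seqid += 1
    if "allosteric" in spec.extras:
        base = np.array([2.0, 45.0, 10.0])
        atoms = [Atom("C1", "C", base), Atom("C2", "C", base + (1.5, 0, 0))]
        hetero.append(HeteroGroup("AL1", het_seqid, monomer.chain_id, atoms))
        het_seqid += 1
    monomer.hetero_groups = hetero

    # noise, then an arbitrary rigid motion of the whole complex
    if spec.noise_sigma > 0:
        for res in monomer.residues:
            for a in res.atoms:
                a.pos = a.pos + rng.normal(0.0, spec.noise_sigma, 3)
        for h in monomer.hetero_groups:
            for a in h.atoms:
                a.pos = a.pos + rng.normal(0.0, spec.noise_sigma, 3)
    if spec.rigid_jumble:
        r = random_rotation(rng)
        t = rng.uniform(-20, 20, 3)
        monomer = monomer.transformed(r, t)

    # expected fingerprint on the final (noisy) coordinates
    final_pocket = pocket_of_domain(monomer)
    final_ligand = None
    if ligand is not None:
        lig_group = monomer.hetero_groups[0]
        mol = Chem.Mol(ligand.mol)
        conf = mol.GetConformer()
        for i, a in enumerate(lig_group.atoms):
            conf.SetAtomPosition(i, Point3D(*map(float, a.pos)))
        final_ligand = record_from_mol(spec.ligand_component, mol,
                                       atom_names=atom_names)
        from .fingerprint import compute_ifp as _cifp
        fp_final = _cifp(final_pocket, final_ligand)
        expected_on_bits = fp_final.on_bits()
    else:
        expected_on_bits = []

    reference = master_pocket_sequence()
    expected_mutations = sorted(
        (slot, reference[slot - 1], aa.upper())
        for slot, aa in spec.pocket_substitutions.items()
        if aa.upper() != reference[slot - 1] and slot not in spec.gap_slots)

    manifest = {
        "source_id": spec.source_id,
        "seed": spec.seed,
        "dfg": f"DFG-{spec.dfg}",
        "alpha_c": _expected_class_alpha_c(spec.alpha_c_distance),
        "gap_slots": sorted(spec.gap_slots),
        "mutations": [list(m) for m in expected_mutations],
        "designed_bits": sorted([s, t] for s, t in expected_bits),
        "incidental_bits": [list(b) for b in incidental_bits],
        "expected_ifp_on_bits": expected_on_bits,
        "occupied_subpockets": list(spec.occupy_subpockets),
        "water_labels": list(spec.waters),
        "n_off_cluster_waters": len(spec.off_cluster_waters),
        "extras": list(spec.extras),
        "apo": ligand is None,
    }
    return FixtureComplex(spec=spec, monomer=monomer, ligand=final_ligand,
                          manifest=manifest)


# ---------------------------------------------------------------------------
# File output

def monomer_to_gemmi(monomer: Monomer) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = monomer.source_id
    model = gemmi.Model(monomer.model_index)
    chain = gemmi.Chain(monomer.chain_id)
    for res in monomer.residues:
        r = gemmi.Residue()
        r.name = res.name
        r.seqid = gemmi.SeqId(res.seqid, " ")
        for a in res.atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*map(float, a.pos))
            at.occ = a.occupancy
            r.add_atom(at)
        chain.add_residue(r)
    for h in monomer.hetero_groups:
        r = gemmi.Residue()
        r.name = h.comp_id
        r.seqid = gemmi.SeqId(h.seqid, " ")
        r.het_flag = "H"
        for a in h.atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*map(float, a.pos))
            r.add_atom(at)
        chain.add_residue(r)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def ccd_text(records: list[LigandRecord]) -> str:
    """Minimal chemical-component-dictionary CIF text for the fixture
    components (atoms, charges, bond orders)."""
    lines = []
    for rec in records:
        lines.append(f"data_{rec.component_id}")
        lines.append("loop_")
        lines.extend(["_chem_comp_atom.comp_id", "_chem_comp_atom.atom_id",
                      "_chem_comp_atom.type_symbol", "_chem_comp_atom.charge"])
        for i, a in enumerate(rec.mol.GetAtoms()):
            lines.append(f"{rec.component_id} {rec.atom_names[i]} "
                         f"{a.GetSymbol().upper()} {a.GetFormalCharge()}")
        lines.append("loop_")
        lines.extend(["_chem_comp_bond.comp_id", "_chem_comp_bond.atom_id_1",
                      "_chem_comp_bond.atom_id_2", "_chem_comp_bond.value_order"])
        order_name = {Chem.BondType.SINGLE: "SING", Chem.BondType.DOUBLE: "DOUB",
                      Chem.BondType.TRIPLE: "TRIP", Chem.BondType.AROMATIC: "AROM"}
        for b in rec.mol.GetBonds():
            lines.append(f"{rec.component_id} {rec.atom_names[b.GetBeginAtomIdx()]} "
                         f"{rec.atom_names[b.GetEndAtomIdx()]} "
                         f"{order_name.get(b.GetBondType(), 'SING')}")
        lines.append("")
    return "\n".join(lines)


def write_ccd_dictionary(records: list[LigandRecord], path: Path) -> None:
    path.write_text(ccd_text(records))


def write_complex(fx: FixtureComplex, out_dir: str | Path) -> dict[str, Path]:
    """Write PDB + ligand SDF/MOL2 + dictionary + manifest; deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    st = monomer_to_gemmi(fx.monomer)
    pdb = out / f"{fx.spec.source_id}.pdb"
    st.write_pdb(str(pdb))
    paths["pdb"] = pdb
    if fx.ligand is not None:
        sdf = out / f"{fx.spec.source_id}_ligand.sdf"
        writer = Chem.SDWriter(str(sdf))
        writer.write(fx.ligand.mol)
        writer.close()
        paths["ligand_sdf"] = sdf
        m2 = out / f"{fx.spec.source_id}_ligand.mol2"
        m2.write_text(mol_to_mol2(fx.ligand.mol, fx.spec.ligand_component,
                                  fx.ligand.atom_names))
        paths["ligand_mol2"] = m2
        ccd = out / f"{fx.spec.source_id}_components.cif"
        write_ccd_dictionary([fx.ligand], ccd)
        paths["dictionary"] = ccd
    protein_m2 = out / f"{fx.spec.source_id}_protein.mol2"
    protein_m2.write_text(monomer_to_mol2(fx.monomer))
    paths["protein_mol2"] = protein_m2
    manifest = out / f"{fx.spec.source_id}_manifest.json"
    manifest.write_text(json.dumps(fx.manifest, indent=1))
    paths["manifest"] = manifest
    return paths


# ---------------------------------------------------------------------------
# Corpora

@dataclass(frozen=True)
class CorpusSample:
    monomer: Monomer
    dfg_label: str               # "DFG-in" / "DFG-out" / "DFG-outlike"
    alpha_c_label: str
    alpha_c_distance: float


_AC_RANGES = {"aC-in": (5.8, 7.0), "aC-outlike": (7.6, 9.0), "aC-out": (9.8, 12.5)}


def generate_corpus(n: int, seed: int = 1, noise_sigma: float = 0.25,
                    jumble: bool = True) -> list[CorpusSample]:
    """Labeled conformation corpus, stratified over the three DFG classes
    (and independently over aC classes); reproducible from the seed."""
    if n < 10:
        raise FixtureSpecError("corpus needs n >= 10")
    rng = np.random.default_rng(seed)
    samples = []
    ac_names = tuple(_AC_RANGES)
    for i in range(n):
        dfg = DFG_CLASSES[i % 3]
        ac = ac_names[(i // 3) % 3]
        d = float(rng.uniform(*_AC_RANGES[ac]))
        spec = FixtureSpec(seed=int(rng.integers(0, 2 ** 31 - 1)),
                           source_id=f"corpus_{i:04d}", dfg=dfg,
                           alpha_c_distance=d, noise_sigma=noise_sigma,
                           rigid_jumble=jumble)
        fx = generate_complex(spec)
        samples.append(CorpusSample(monomer=fx.monomer, dfg_label=f"DFG-{dfg}",
                                    alpha_c_label=ac, alpha_c_distance=d))
    return samples


def generate_subpocket_corpus(n: int, seed: int = 1,
                              ) -> list[tuple[np.ndarray, set[str]]]:
    """Synthetic ligand atom clouds with geometric subpocket labels.

    Each sample occupies one to three subpocket spheres; labels are read
    back from the geometry so they are exact by construction.
    """
    rng = np.random.default_rng(seed)
    names = list(SUBPOCKET_SPHERES)
    corpus = []
    for _ in range(n):
        k = int(rng.integers(1, 4))
        chosen = rng.choice(len(names), size=k, replace=False)
        atoms = []
        for ci in chosen:
            center, radius = SUBPOCKET_SPHERES[names[int(ci)]]
            m = int(rng.integers(5, 10))
            vecs = rng.normal(size=(m, 3))
            vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
            radii = radius * 0.65 * rng.uniform(0, 1, m) ** (1 / 3)
            atoms.append(np.asarray(center) + vecs * radii[:, None])
        coords = np.vstack(atoms)
        corpus.append((coords, subpocket_labels_for(coords)))
    return corpus


def generate_water_corpus(n_structures: int, seed: int = 1,
                          jitter: float = 0.3,
                          ) -> list[tuple[np.ndarray, str]]:
    """Water observations for cluster derivation: each synthetic structure
    contributes jittered waters at a subset of the conserved sites; the
    O1/O2 sites appear only in DFG-out structures."""
    rng = np.random.default_rng(seed)
    out = []
    labels = list(TRUE_WATER_SITES)
    for i in range(n_structures):
        dfg = DFG_CLASSES[i % 3]
        waters = []
        for label in labels:
            if label in DFG_OUT_SITES and dfg != "out":
                continue
            if rng.uniform() < 0.75:
                waters.append(np.asarray(TRUE_WATER_SITES[label])
                              + rng.normal(0, jitter, 3))
        if waters:
            out.append((np.array(waters), f"DFG-{dfg}"))
    return out
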