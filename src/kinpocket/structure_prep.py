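"""Structure reading, monomer splitting and entity classification.

Entries are split into single-model, single-chain monomers (the unit the
rest of the pipeline consumes), alternate locations are resolved to the
highest-occupancy conformer, and every hetero group is routed to exactly
one entity category: water, ion, cofactor, organometallic, or ligand —
with ligands further divided into orthosteric (contacting the catalytic
cleft) and allosteric.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .config import DEFAULT_CONFIG, EntityConfig
from .errors import EmptyEntryError, FormatError, InputError
from .ligands import LigandRecord, curate_ligand_topology
from .model import Atom, HeteroGroup, Monomer, Residue
from .pocket_mapping import PocketAlignment
from .residues import AA1


def filter_homolog_hits(hits: list[tuple[float, float]],
                        min_identity: float = 70.0,
                        max_evalue: float = 1e-3) -> list[int]:
    """Indices of homology-search hits accepted for processing
    (identity >= 70% and e-value <= 0.001, boundaries inclusive)."""
    accepted = []
    for i, (identity, evalue) in enumerate(hits):
        if not 0.0 <= identity <= 100.0:
            raise InputError(f"hit {i}: identity {identity} outside [0, 100]")
        if evalue < 0.0:
            raise InputError(f"hit {i}: negative e-value {evalue}")
        if identity >= min_identity and evalue <= max_evalue:
            accepted.append(i)
    return accepted


def _resolve_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties broken by
    the alphabetically first alt-loc identifier."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key_new = (-atom.occ, atom.altloc or "~")
        key_old = (-prev.occ, prev.altloc or "~")
        if key_new < key_old:
            by_name[atom.name] = atom
    return list(by_name.values())


def _to_atom(a: gemmi.Atom) -> Atom:
    return Atom(name=a.name, element=a.element.name.upper() or a.name[0],
                pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
                altloc=a.altloc or "", occupancy=a.occ)


def split_entry(structure_file: str | Path,
                source_id: str | None = None) -> list[Monomer]:
    """Split a PDB/mmCIF entry into monomers, one per (model, chain) pair
    with protein content.  Hetero groups stay with their chain; hetero
    groups from ligand-only chains are attached to the single protein
    chain of the model when that is unambiguous.
    """
    path = Path(structure_file)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise EmptyEntryError(f"{path.name}: no models")
    st.setup_entities()
    source = source_id or path.stem
    monomers: list[Monomer] = []
    for mi, model in enumerate(st, start=1):
        chains: dict[str, tuple[list[Residue], list[HeteroGroup]]] = {}
        for chain in model:
            residues: list[Residue] = []
            hetero: list[HeteroGroup] = []
            for res in chain:
                atoms = [_to_atom(a) for a in _resolve_altlocs(res)]
                if res.name in AA1 and any(a.name == "CA" for a in atoms):
                    residues.append(Residue(res.name, res.seqid.num, atoms))
                else:
                    hetero.append(HeteroGroup(res.name, res.seqid.num,
                                              chain.name, atoms))
            chains[chain.name] = (residues, hetero)
        protein_chains = [c for c, (r, _) in chains.items() if r]
        for cname in protein_chains:
            residues, hetero = chains[cname]
            hetero = list(hetero)
            if len(protein_chains) == 1:
                for other, (r, h) in chains.items():
                    if other != cname and not r:
                        hetero.extend(h)
            monomers.append(Monomer(source_id=source, model_index=mi,
                                    chain_id=cname, residues=residues,
                                    hetero_groups=hetero))
    if not monomers:
        raise EmptyEntryError(f"{path.name}: no protein chains")
    return monomers


@dataclass
class EntitySet:
    """All hetero content of one monomer, each group in exactly one
    category."""

    protein: Monomer
    orthosteric: list[tuple[HeteroGroup, LigandRecord]] = field(default_factory=list)
    allosteric: list[tuple[HeteroGroup, LigandRecord]] = field(default_factory=list)
    waters: list[HeteroGroup] = field(default_factory=list)
    ions: list[HeteroGroup] = field(default_factory=list)
    cofactors: list[HeteroGroup] = field(default_factory=list)
    organometallics: list[HeteroGroup] = field(default_factory=list)

    @property
    def orthosteric_ligand(self) -> LigandRecord | None:
        """Primary orthosteric ligand (largest heavy-atom count)."""
        if not self.orthosteric:
            return None
        return max(self.orthosteric, key=lambda t: t[1].n_heavy)[1]

    @property
    def n_groups(self) -> int:
        return (len(self.orthosteric) + len(self.allosteric) + len(self.waters)
                + len(self.ions) + len(self.cofactors) + len(self.organometallics))

    def water_coords(self) -> np.ndarray:
        coords = [a.pos for w in self.waters for a in w.atoms
                  if a.element.upper() == "O"]
        return np.array(coords) if coords else np.empty((0, 3))


def _is_ion(group: HeteroGroup, cfg: EntityConfig) -> bool:
    heavy = [a for a in group.atoms if a.element.upper() != "H"]
    if len(heavy) != 1:
        return False
    el = heavy[0].element.upper()
    return el in cfg.metal_elements or el in cfg.halide_elements


def _is_organometallic(group: HeteroGroup, cfg: EntityConfig) -> bool:
    elements = {a.element.upper() for a in group.atoms}
    return bool(elements & set(cfg.metal_elements)) and "C" in elements


def classify_entities(monomer: Monomer, pocket: PocketAlignment,
                      dictionary=None,
                      cfg: EntityConfig | None = None) -> EntitySet:
    """Route every hetero group to one category (fixed rule order: water,
    ion, cofactor, organometallic, ligand) and split ligands into
    orthosteric / allosteric by heavy-atom contact (<= 4.0 A default)
    with the pocket residues of the catalytic cleft."""
    cfg = cfg or DEFAULT_CONFIG.entities
    out = EntitySet(protein=monomer)
    pocket_coords = []
    for slot in pocket.slots:
        if not slot.is_gap:
            pocket_coords.extend(a.pos for a in slot.residue.atoms
                                 if a.element.upper() != "H")
    pocket_coords = np.array(pocket_coords) if pocket_coords else np.empty((0, 3))
    for group in monomer.hetero_groups:
        comp = group.comp_id.upper()
        if comp in cfg.water_components:
            out.waters.append(group)
            continue
        if _is_ion(group, cfg):
            out.ions.append(group)
            continue
        if comp in cfg.cofactor_components:
            out.cofactors.append(group)
            continue
        if _is_organometallic(group, cfg):
            out.organometallics.append(group)
            continue
        try:
            record = curate_ligand_topology(group, dictionary,
                                            cfg.water_components)
        except InputError as exc:
            warnings.warn(f"group {comp} {group.seqid}: {exc}; kept as "
                          "unclassified ligand without topology")
            continue
        heavy = np.array([a.pos for a in group.atoms
                          if a.element.upper() != "H"])
        orthosteric = False
        if len(pocket_coords) and len(heavy):
            d2 = ((heavy[:, None, :] - pocket_coords[None, :, :]) ** 2).sum(-1)
            orthosteric = bool((d2 <= cfg.orthosteric_contact ** 2).any())
        (out.orthosteric if orthosteric else out.allosteric).append((group, record))
    return out


def entity_manifest_csv(entities: EntitySet) -> str:
    """Entity overview as CSV (one row per hetero group)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["category", "component", "seqid", "chain", "n_heavy_atoms"])
    rows = ([("orthosteric_ligand", g) for g, _ in entities.orthosteric]
            + [("allosteric_ligand", g) for g, _ in entities.allosteric]
            + [("water", g) for g in entities.waters]
            + [("ion", g) for g in entities.ions]
            + [("cofactor", g) for g in entities.cofactors]
            + [("organometallic", g) for g in entities.organometallics])
    for cat, g in rows:
        writer.writerow([cat, g.comp_id, g.seqid, g.chain_id, g.n_heavy])
    return buf.getvalue()
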