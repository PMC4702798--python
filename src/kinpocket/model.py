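"""Lightweight in-memory structure model.

A :class:`Monomer` is the unit the whole pipeline operates on: exactly one
model and one chain, protein residues plus residue-grouped hetero atoms.
Monomers come either from file parsing (:mod:`kinpocket.structure_prep`)
or from the synthetic fixture generator (:mod:`kinpocket.fixtures`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .residues import AA1, atom_element


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    name: str                      # 3-letter code
    seqid: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return AA1.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.pos

    def has_atom(self, name: str) -> bool:
        return self.atom(name) is not None

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])


@dataclass
class HeteroGroup:
    """One hetero residue (ligand, water, ion, cofactor ...)."""

    comp_id: str
    seqid: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    @property
    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if a.element.upper() != "H")


@dataclass
class Monomer:
    """Single-model, single-chain protein unit with attached hetero groups."""

    source_id: str
    model_index: int
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    hetero_groups: list[HeteroGroup] = field(default_factory=list)

    def __post_init__(self):
        if self.model_index < 1:
            raise ValueError("model_index must be >= 1")

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_by_seqid(self, seqid: int) -> Residue | None:
        for r in self.residues:
            if r.seqid == seqid:
                return r
        return None

    def protein_atoms(self) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.residues for a in r.atoms]

    def protein_coords(self) -> np.ndarray:
        return np.array([a.pos for _, a in self.protein_atoms()])

    def transformed(self, r: np.ndarray, t: np.ndarray) -> "Monomer":
        """Copy with a rigid transform applied to every atom."""
        def tx(atom: Atom) -> Atom:
            return Atom(atom.name, atom.element, r @ atom.pos + t,
                        atom.altloc, atom.occupancy)

        return Monomer(
            source_id=self.source_id,
            model_index=self.model_index,
            chain_id=self.chain_id,
            residues=[Residue(res.name, res.seqid, [tx(a) for a in res.atoms])
                      for res in self.residues],
            hetero_groups=[HeteroGroup(h.comp_id, h.seqid, h.chain_id,
                                       [tx(a) for a in h.atoms])
                           for h in self.hetero_groups],
        )


def make_atom(name: str, pos, element: str | None = None, **kw) -> Atom:
    return Atom(name, element or atom_element(name), np.asarray(pos, float), **kw)
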