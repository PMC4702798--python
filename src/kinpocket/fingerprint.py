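"""Kinase-ligand interaction fingerprints (IFP).

Seven interaction types are evaluated between each of the 85 pocket
residues and the bound ligand, giving a fixed-length 595-bit string:
per-residue blocks of (hydrophobic, aromatic face-to-face, aromatic
edge-to-face, H-bond protein-donor→ligand-acceptor, H-bond
protein-acceptor←ligand-donor, ionic protein-positive→ligand-negative,
ionic protein-negative→ligand-positive), protein perspective first.
Gapped pocket slots contribute seven zeroes so fingerprints from gapped
structures remain directly comparable.

Geometry is heavy-atom only; hydrogen positions are idealized through the
donor's heavy-atom antecedents (the donor angle is measured at the donor
between an antecedent and the acceptor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, InteractionConfig
from .errors import InputError
from .ligands import LigandRecord
from .model import Residue
from .pocket_mapping import N_SLOTS, PocketAlignment
from .residues import (APOLAR_ATOMS, AROMATIC_RINGS, CHARGE_CENTERS,
                       SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS)

N_TYPES = 7
N_BITS = N_SLOTS * N_TYPES

INTERACTION_TYPES = ("hydrophobic", "aromatic_f2f", "aromatic_e2f",
                     "hbond_donor", "hbond_acceptor",
                     "ionic_positive", "ionic_negative")
_TYPE_INDEX = {name: i for i, name in enumerate(INTERACTION_TYPES)}


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1))))


@dataclass
class ResidueInteractionSites:
    """Typed interaction sites of one pocket residue."""

    apolar: np.ndarray                       # (n, 3)
    rings: list[tuple[np.ndarray, np.ndarray]]   # (centroid, normal)
    donors: list[tuple[np.ndarray, list[np.ndarray]]]  # (donor, antecedents)
    acceptors: np.ndarray                    # (n, 3)
    charges: list[tuple[np.ndarray, int]]    # (center, sign)


def residue_sites(residue: Residue, prev_c: np.ndarray | None = None) -> ResidueInteractionSites:
    """Collect the typed heavy-atom interaction sites of a residue.

    ``prev_c`` is the preceding residue's carbonyl carbon, used as a second
    antecedent for the backbone amide donor.
    """
    name = residue.name
    apolar = [residue.coord(a) for a in APOLAR_ATOMS.get(name, ())
              if residue.has_atom(a)]
    rings = []
    for cycle in AROMATIC_RINGS.get(name, ()):
        coords = [residue.coord(a) for a in cycle if residue.has_atom(a)]
        if len(coords) == len(cycle):
            rings.append(_ring_geometry(np.array(coords)))
    donors: list[tuple[np.ndarray, list[np.ndarray]]] = []
    n_pos = residue.coord("N")
    if n_pos is not None and name != "PRO":
        ante = [p for p in (residue.coord("CA"), prev_c) if p is not None]
        donors.append((n_pos, ante))
    for donor_name, antecedents in SIDECHAIN_DONORS.get(name, {}).items():
        dpos = residue.coord(donor_name)
        if dpos is None:
            continue
        ante = [residue.coord(a) for a in antecedents if residue.has_atom(a)]
        donors.append((dpos, ante))
    acceptors = [residue.coord("O")] if residue.has_atom("O") else []
    acceptors += [residue.coord(a) for a in SIDECHAIN_ACCEPTORS.get(name, ())
                  if residue.has_atom(a)]
    charges = [(residue.coord(a), sign) for a, sign in CHARGE_CENTERS.get(name, ())
               if residue.has_atom(a)]
    return ResidueInteractionSites(
        apolar=np.array(apolar) if apolar else np.empty((0, 3)),
        rings=rings, donors=donors,
        acceptors=np.array([a for a in acceptors if a is not None])
        if acceptors else np.empty((0, 3)),
        charges=charges)


@dataclass
class LigandInteractionSites:
    apolar: np.ndarray
    rings: list[tuple[np.ndarray, np.ndarray]]
    donors: list[tuple[np.ndarray, list[np.ndarray]]]
    acceptors: np.ndarray
    charges: list[tuple[np.ndarray, int]]


def ligand_sites(ligand: LigandRecord) -> LigandInteractionSites:
    coords = ligand.coords()
    apolar_idx = ligand.apolar_atoms()
    rings = []
    for ring in ligand.aromatic_rings():
        rings.append(_ring_geometry(coords[list(ring)]))
    donors = [(coords[i], [coords[j] for j in ante])
              for i, ante in ligand.donor_atoms()]
    acc_idx = ligand.acceptor_atoms()
    return LigandInteractionSites(
        apolar=coords[apolar_idx] if apolar_idx else np.empty((0, 3)),
        rings=rings, donors=donors,
        acceptors=coords[acc_idx] if acc_idx else np.empty((0, 3)),
        charges=ligand.charge_centers())


def _hbond(donors, acceptors: np.ndarray, cfg: InteractionConfig) -> bool:
    if len(acceptors) == 0:
        return False
    for dpos, antecedents in donors:
        d = np.linalg.norm(acceptors - dpos, axis=1)
        for acc in acceptors[d <= cfg.hbond_max]:
            if not antecedents:
                return True         # no antecedent resolved: distance-only
            if max(_angle(a, dpos, acc) for a in antecedents) >= cfg.hbond_donor_angle_min:
                return True
    return False


def detect_interactions(res_sites: ResidueInteractionSites,
                        lig_sites: LigandInteractionSites,
                        cfg: InteractionConfig | None = None) -> np.ndarray:
    """Seven-bit interaction block between one residue and the ligand."""
    cfg = cfg or DEFAULT_CONFIG.interactions
    bits = np.zeros(N_TYPES, dtype=np.uint8)
    # hydrophobic: any apolar-apolar pair within cutoff
    if len(res_sites.apolar) and len(lig_sites.apolar):
        d = np.linalg.norm(res_sites.apolar[:, None, :] - lig_sites.apolar[None, :, :],
                           axis=-1)
        if (d <= cfg.hydrophobic_max).any():
            bits[0] = 1
    # aromatic
    for pc, pn in res_sites.rings:
        for lc, ln in lig_sites.rings:
            dist = float(np.linalg.norm(pc - lc))
            cosang = abs(float(np.clip(np.dot(pn, ln), -1, 1)))
            ang = float(np.degrees(np.arccos(cosang)))
            if dist <= cfg.aromatic_f2f_max and ang <= cfg.aromatic_f2f_angle_max:
                bits[1] = 1
            lo, hi = cfg.aromatic_e2f_angle_range
            if dist <= cfg.aromatic_e2f_max and lo <= ang <= hi:
                bits[2] = 1
    # hydrogen bonds, both directions
    if _hbond(res_sites.donors, lig_sites.acceptors, cfg):
        bits[3] = 1
    if _hbond(lig_sites.donors, res_sites.acceptors, cfg):
        bits[4] = 1
    # ionic
    for pp, psign in res_sites.charges:
        for lp, lsign in lig_sites.charges:
            if psign * lsign < 0 and np.linalg.norm(pp - lp) <= cfg.ionic_max:
                if psign > 0:
                    bits[5] = 1
                else:
                    bits[6] = 1
    return bits


@dataclass(frozen=True)
class InteractionFingerprint:
    """595-bit interaction fingerprint (85 residues x 7 types)."""

    bits: np.ndarray
    apo: bool = False

    def __post_init__(self):
        if self.bits.shape != (N_BITS,):
            raise InputError(f"fingerprint must have {N_BITS} bits")

    def __len__(self) -> int:
        return N_BITS

    def block(self, index: int) -> np.ndarray:
        if not 1 <= index <= N_SLOTS:
            raise InputError(f"slot index out of 1..{N_SLOTS}")
        return self.bits[(index - 1) * N_TYPES: index * N_TYPES]

    def get(self, index: int, interaction: str) -> int:
        return int(self.block(index)[_TYPE_INDEX[interaction]])

    def on_bits(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.bits)]

    def count(self) -> int:
        return int(self.bits.sum())

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstring: str, apo: bool = False) -> "InteractionFingerprint":
        bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexstring), dtype=np.uint8))
        return cls(bits=bits[:N_BITS].astype(np.uint8), apo=apo)

    @classmethod
    def from_on_bits(cls, on: list[int], apo: bool = False) -> "InteractionFingerprint":
        bits = np.zeros(N_BITS, dtype=np.uint8)
        bits[list(on)] = 1
        return cls(bits=bits, apo=apo)


def compute_ifp(pocket: PocketAlignment, ligand: LigandRecord | None,
                cfg: InteractionConfig | None = None) -> InteractionFingerprint:
    """Full-pocket fingerprint: 85 blocks in slot order; gaps contribute
    seven zeroes; apo structures give the flagged all-zero fingerprint."""
    if ligand is None:
        return InteractionFingerprint(bits=np.zeros(N_BITS, dtype=np.uint8), apo=True)
    cfg = cfg or DEFAULT_CONFIG.interactions
    lsites = ligand_sites(ligand)
    bits = np.zeros(N_BITS, dtype=np.uint8)
    seqid_index = {}
    for slot in pocket.slots:
        if slot.residue is not None:
            seqid_index[slot.seqid] = slot.residue
    for slot in pocket.slots:
        if slot.is_gap:
            continue
        prev = seqid_index.get(slot.seqid - 1)
        prev_c = prev.coord("C") if prev is not None else None
        rsites = residue_sites(slot.residue, prev_c=prev_c)
        bits[(slot.index - 1) * N_TYPES: slot.index * N_TYPES] = \
            detect_interactions(rsites, lsites, cfg)
    return InteractionFingerprint(bits=bits, apo=False)


def ifp_similarity(a: InteractionFingerprint, b: InteractionFingerprint) -> float:
    """Tanimoto coefficient over set bits; 1.0 when both are empty."""
    if len(a.bits) != len(b.bits):
        raise InputError("fingerprint length mismatch")
    inter = int(np.sum((a.bits & b.bits) > 0))
    union = int(np.sum((a.bits | b.bits) > 0))
    if union == 0:
        return 1.0
    return inter / union


@dataclass(frozen=True)
class InteractionPattern:
    """Per-slot interaction constraints: (slot index, type, required)."""

    constraints: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self):
        for idx, typ, req in self.constraints:
            if not 1 <= idx <= N_SLOTS:
                raise InputError(f"pattern slot index {idx} out of 1..{N_SLOTS}")
            if typ not in _TYPE_INDEX:
                raise InputError(f"unknown interaction type {typ!r}")
            if req not in ("present", "absent", "any"):
                raise InputError(f"requirement must be present/absent/any, got {req!r}")


def match_pattern(fp: InteractionFingerprint, pattern: InteractionPattern) -> bool:
    """True iff every 'present' constraint bit is set and every 'absent'
    constraint bit is clear (empty patterns match vacuously)."""
    for idx, typ, req in pattern.constraints:
        bit = fp.get(idx, typ)
        if req == "present" and bit != 1:
            return False
        if req == "absent" and bit != 0:
            return False
    return True
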