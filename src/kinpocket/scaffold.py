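"""Geometric kinase-pocket scaffold: the master structural frame.

The master frame is a synthetic, idealized catalytic-domain geometry: each
binding-site region is laid out as a rigid segment (3.8 A Ca spacing)
around a central ligand cavity, with side chains placed analytically.
It is *geometric, not physical* — no folding or energetics — but it fixes
a reproducible reference coordinate system: superposition targets, the
axis convention for the DFG side-chain vectors, subpocket and water-site
positions are all expressed in this frame.

Frame conventions (angstroms):
  * the ligand cavity is centred near the origin;
  * +x points toward the hinge (front cleft), -x toward the back cleft;
  * +z points toward the G-rich loop roof, -z toward the catalytic loop;
  * y is the lateral axis used by the DFG side-chain y-vector descriptors.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .errors import FixtureSpecError, InputError
from .geometry import unit
from .model import Atom, Monomer, Residue, make_atom
from .pocket_mapping import (GAP, N_SLOTS, PocketAlignment, PocketSlot,
                             RegionTable, load_region_table, master_consensus,
                             master_pocket_sequence)
from .residues import AA3, SIDECHAIN_ATOMS, atom_element, expected_heavy_atoms

CA_SPACING = 3.8
POCKET_CENTER = np.zeros(3)

# Region segments: start Ca position and unit direction in the master frame.
REGION_SEGMENTS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "I":      ((3.0, -16.0, 12.0), (0, 1, 0)),
    "g.l":    ((5.0, -5.0, 6.5), (-0.971, 0.240, 0.0)),
    "II":     ((-1.5, -13.0, 13.5), (0, 1, 0)),
    "III":    ((-14.0, -16.0, 12.5), (0, 1, 0)),
    "aC":     ((-8.0, -15.2, 2.0), (0, 1, 0)),
    "b.l":    ((-3.5, -20.0, 3.0), (0, 1, 0)),
    "IV":     ((1.5, -19.5, 5.0), (0, 1, 0)),
    "V":      ((4.5, -17.4, 1.0), (0, 1, 0)),
    "GK":     ((4.5, -6.0, 1.0), (0, 1, 0)),
    "hinge":  ((8.5, -3.8, 0.0), (0, 1, 0)),
    "linker": ((9.0, 7.2, -1.5), (0, 0.6, -0.8)),
    "aD":     ((5.0, 9.5, -6.0), (0, -1, 0)),
    "aE":     ((-15.0, 8.0, -14.0), (0, -1, 0)),
    "VI":     ((-11.5, -13.0, -10.5), (0, 1, 0)),
    "c.l":    ((-7.0, -13.5, -6.5), (0, 1, 0)),
    "VII":    ((-1.5, -20.9, -4.5), (0, 1, 0)),
    "VIII":   ((-1.5, -8.6, -4.5), (0, 1, 0)),
    "xDFG":   ((-4.0, -6.8, -3.0), (0, 1, 0)),
    "a.l":    ((-2.5, 7.5, -4.0), (0.55, 0.8, -0.25)),
}

# Side-chain direction targets for pocket-lining residues (the default is
# outward, away from the cavity, keeping the ligand cavity clean).
_INWARD_TARGETS: dict[int, tuple[float, float, float]] = {
    24: (-6.0, 4.0, 1.0),   # aC glutamate reaches toward the xDFG motif
    36: (0.0, 0.0, 0.0),     # b.l valine lines the gate area
    45: (1.5, -2.0, 0.0),    # gatekeeper points into the gate area
}

# Region-level side-chain growth directions.  Parallel neighbouring
# segments would cross if every side chain simply grew radially outward,
# so crowded regions are combed onto clear headings.
_REGION_SIDE_DIRS: dict[str, tuple[float, float, float]] = {
    "I":     (0.2, 0.0, 0.98),
    "g.l":   (0.0, 0.0, 1.0),     # roof residues point up, cavity stays clean
    "II":    (0.0, 0.0, 1.0),
    "III":   (-0.3, 0.0, 0.95),
    "aC":    (-0.98, 0.0, 0.2),
    "b.l":   (0.2, 0.0, 0.98),
    "IV":    (0.9, -0.35, 0.35),
    "V":     (0.9, 0.0, 0.44),
    "aD":    (0.7, 0.0, -0.7),
    "aE":    (-0.6, 0.0, -0.8),
    "VI":    (0.1, 0.45, -0.89),
    "c.l":   (0.5, 0.0, -0.87),
    "VII":   (0.3, 0.0, -0.95),
    "VIII":  (0.3, 0.0, -0.95),
}

# DFG side-chain direction conventions per conformation class: the aspartate
# (slot 81) and phenylalanine (slot 82) chi-directions.  DFG-in points the
# Phe ring into the back cleft (yF < 0) and the Asp toward the ATP site
# (yD > 0); DFG-out swaps them; DFG-outlike tucks both along +z.
DFG_DIRECTIONS: dict[str, dict[int, tuple[float, float, float]]] = {
    "in":      {81: (0.20, 0.90, 0.35), 82: (-0.50, -0.75, 0.45)},
    "out":     {81: (-0.30, -0.85, 0.40), 82: (0.35, 0.80, 0.25)},
    "outlike": {81: (0.25, 0.10, 0.96), 82: (0.30, -0.60, -0.50)},
}

DFG_CLASSES = ("in", "out", "outlike")

# Distance |Ca(E.aC.24) - Ca(F.xDFG.82)| in the unmodified master layout.
_AC_BASE_VECTOR = np.array([-4.0, -0.8, 5.0])

# Filler (non-pocket) segments are parked on a rail far outside the pocket.
_FILLER_BASE = np.array([28.0, -24.0, 22.0])


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    ax = unit(axis)
    th = np.radians(angle_deg_)
    return (v * np.cos(th) + np.cross(ax, v) * np.sin(th)
            + ax * np.dot(ax, v) * (1 - np.cos(th)))


def _chain(ca: np.ndarray, d: np.ndarray, u: np.ndarray, n: int) -> list[np.ndarray]:
    """Zigzag aliphatic chain positions starting at CB."""
    return [ca + (1.53 + 1.30 * k) * d + (0.45 * (k % 2)) * u for k in range(n)]


def _splay(tip: np.ndarray, d: np.ndarray, u: np.ndarray, bond: float) -> tuple[np.ndarray, np.ndarray]:
    a = tip + bond * (0.45 * d + 0.89 * u)
    b = tip + bond * (0.45 * d - 0.89 * u)
    return a, b


def _hexagon(center: np.ndarray, d: np.ndarray, u: np.ndarray,
             radius: float, angles: list[float]) -> list[np.ndarray]:
    return [center + radius * (np.cos(np.radians(t)) * d + np.sin(np.radians(t)) * u)
            for t in angles]


def build_sidechain(aa3: str, ca: np.ndarray, d: np.ndarray,
                    u: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Analytic side-chain heavy-atom positions for residue type ``aa3``
    grown from ``ca`` along unit direction ``d`` (``u`` a unit perpendicular)."""
    names = SIDECHAIN_ATOMS[aa3]
    if not names:
        return []
    out: dict[str, np.ndarray] = {}
    cb = ca + 1.53 * d
    out["CB"] = cb
    if aa3 in ("ALA",):
        pass
    elif aa3 in ("SER", "CYS"):
        out[names[1]] = _chain(ca, d, u, 2)[1]
    elif aa3 == "THR":
        out["OG1"] = cb + 1.42 * (0.55 * d + 0.835 * u)
        out["CG2"] = cb + 1.53 * (0.55 * d - 0.835 * u)
    elif aa3 == "VAL":
        out["CG1"] = cb + 1.53 * (0.55 * d + 0.835 * u)
        out["CG2"] = cb + 1.53 * (0.55 * d - 0.835 * u)
    elif aa3 == "LEU":
        cg = _chain(ca, d, u, 2)[1]
        out["CG"] = cg
        out["CD1"] = cg + 1.53 * (0.55 * d + 0.835 * u)
        out["CD2"] = cg + 1.53 * (0.55 * d - 0.835 * u)
    elif aa3 == "ILE":
        out["CG1"] = cb + 1.53 * (0.55 * d + 0.835 * u)
        out["CG2"] = cb + 1.53 * (0.55 * d - 0.835 * u)
        out["CD1"] = out["CG1"] + 1.53 * d
    elif aa3 == "MET":
        pos = _chain(ca, d, u, 4)
        for n_, p in zip(("CB", "CG", "SD", "CE"), pos):
            out[n_] = p
    elif aa3 == "PRO":
        out["CG"] = cb + 1.50 * (0.20 * d + 0.98 * u)
        out["CD"] = out["CG"] + 1.50 * (-0.90 * d + 0.30 * u)
    elif aa3 == "ASP":
        cg = _chain(ca, d, u, 2)[1]
        out["CG"] = cg
        out["OD1"], out["OD2"] = _splay(cg, d, u, 1.25)
    elif aa3 == "ASN":
        cg = _chain(ca, d, u, 2)[1]
        out["CG"] = cg
        out["OD1"], out["ND2"] = _splay(cg, d, u, 1.30)
    elif aa3 == "GLU":
        pos = _chain(ca, d, u, 3)
        out["CG"], out["CD"] = pos[1], pos[2]
        out["OE1"], out["OE2"] = _splay(pos[2], d, u, 1.25)
    elif aa3 == "GLN":
        pos = _chain(ca, d, u, 3)
        out["CG"], out["CD"] = pos[1], pos[2]
        out["OE1"], out["NE2"] = _splay(pos[2], d, u, 1.30)
    elif aa3 == "LYS":
        pos = _chain(ca, d, u, 5)
        for n_, p in zip(("CB", "CG", "CD", "CE", "NZ"), pos):
            out[n_] = p
    elif aa3 == "ARG":
        pos = _chain(ca, d, u, 4)
        for n_, p in zip(("CB", "CG", "CD", "NE"), pos):
            out[n_] = p
        cz = pos[3] + 1.33 * d
        out["CZ"] = cz
        out["NH1"], out["NH2"] = _splay(cz, d, u, 1.33)
    elif aa3 == "HIS":
        center = ca + 3.70 * d
        ring = _hexagon(center, d, u, 1.17, [180, 108, 36, -36, -108])
        for n_, p in zip(("CG", "ND1", "CE1", "NE2", "CD2"), ring):
            out[n_] = p
    elif aa3 in ("PHE", "TYR"):
        center = ca + 3.92 * d
        ring = _hexagon(center, d, u, 1.39, [180, 120, 60, 0, -60, -120])
        for n_, p in zip(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), ring):
            out[n_] = p
        if aa3 == "TYR":
            out["OH"] = out["CZ"] + 1.36 * d
    elif aa3 == "TRP":
        c5 = ca + 3.50 * d
        ring5 = _hexagon(c5, d, u, 1.17, [180, 110, 38, -38, -110])
        for n_, p in zip(("CG", "CD1", "NE1", "CE2", "CD2"), ring5):
            out[n_] = p
        mid = 0.5 * (out["CE2"] + out["CD2"])
        e = unit(mid - c5)
        h6 = mid + 1.20 * e
        normal = np.cross(out["CE2"] - h6, out["CD2"] - h6)
        prev = out["CD2"] - h6
        for n_ in ("CE3", "CZ3", "CH2", "CZ2"):
            prev = _rodrigues(prev, normal, 60.0)
            out[n_] = h6 + prev
    else:  # pragma: no cover - table is exhaustive
        raise InputError(f"unknown residue type {aa3}")
    return [(n_, out[n_]) for n_ in names]


def _backbone(ca: np.ndarray, t: np.ndarray, parity: int) -> list[tuple[str, np.ndarray]]:
    w = unit(np.cross(t, [0.0, 0.0, 1.0]) if abs(t[2]) < 0.9
             else np.cross(t, [1.0, 0.0, 0.0]))
    m = w * (1 if parity % 2 == 0 else -1)
    w2 = unit(np.cross(t, m))
    n = ca - 1.20 * t + 0.55 * m
    c = ca + 1.20 * t + 0.55 * m
    o = c + 1.23 * w2
    return [("N", n), ("CA", ca.copy()), ("C", c), ("O", o)]


def _sidechain_frame(ca: np.ndarray, t: np.ndarray, slot: int | None,
                     dfg: str, region: str | None = None,
                     inward: dict[int, tuple[float, float, float]] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Direction (d) and perpendicular (u) for growing the side chain.

    Priority: DFG-class convention (slots 81/82) > per-slot inward target >
    region heading > radially outward."""
    targets = dict(_INWARD_TARGETS)
    if inward:
        targets.update(inward)
    target = None
    d = None
    if slot is not None:
        if slot in (81, 82):
            target = ca + 4.0 * np.asarray(DFG_DIRECTIONS[dfg][slot])
        elif slot in targets:
            target = np.asarray(targets[slot], float)
    if target is None and region in _REGION_SIDE_DIRS:
        d = unit(np.asarray(_REGION_SIDE_DIRS[region], float))
    if d is None:
        if target is None:
            v = ca - POCKET_CENTER
            d = unit(v) if np.linalg.norm(v) > 1e-6 else np.array([0.0, 0.0, 1.0])
        else:
            d = unit(target - ca)
    # keep d from degenerating onto the chain direction
    if abs(np.dot(d, t)) > 0.99:
        d = unit(d + 0.3 * unit(np.cross(t, [0.0, 0.0, 1.0])))
    u = unit(np.cross(d, t))
    return d, u


def region_ca(table: RegionTable, slot: int) -> np.ndarray:
    """Master-frame Ca position of a pocket slot."""
    region = table.region_of(slot)
    first = table.slots_in_region(region)[0]
    start, direction = REGION_SEGMENTS[region]
    return np.asarray(start, float) + (slot - first) * CA_SPACING * unit(np.asarray(direction, float))


def build_domain(
    pocket_substitutions: dict[int, str] | None = None,
    dfg: str = "in",
    alpha_c_distance: float | None = None,
    gloop_lift: float = 0.0,
    delete_slots: tuple[int, ...] = (),
    truncate_atoms: dict[int, tuple[str, ...]] | None = None,
    inward_slots: dict[int, tuple[float, float, float]] | None = None,
    seqid_start: int = 101,
    source_id: str = "synthetic",
    chain_id: str = "A",
) -> Monomer:
    """Build a full synthetic catalytic-domain monomer in the master frame.

    Parameters mirror the fixture knobs: pocket sequence substitutions,
    DFG conformation class, target aC distance (|Ca E.aC.24 - Ca F.xDFG.82|),
    a G-rich-loop lift along the loop-to-catalytic-loop axis, slots deleted
    outright (missing residues) and per-slot atom-name truncations.
    """
    if dfg not in DFG_CLASSES:
        raise FixtureSpecError(f"unknown DFG class {dfg!r}")
    table = load_region_table()
    cons = master_consensus()
    subs = pocket_substitutions or {}
    trunc = truncate_atoms or {}
    slot_of_col = {table.column_of(i): i for i in range(1, N_SLOTS + 1)}

    # per-region rigid adjustments
    shift: dict[str, np.ndarray] = {}
    if alpha_c_distance is not None:
        base = np.linalg.norm(_AC_BASE_VECTOR)
        shift["aC"] = (alpha_c_distance - base) * unit(_AC_BASE_VECTOR)
    if gloop_lift:
        gl_start, gl_dir = REGION_SEGMENTS["g.l"]
        gl_centroid = np.asarray(gl_start) + 2.5 * CA_SPACING * unit(np.asarray(gl_dir, float))
        cl_start, cl_dir = REGION_SEGMENTS["c.l"]
        cl_centroid = np.asarray(cl_start) + 3.5 * CA_SPACING * unit(np.asarray(cl_dir, float))
        shift["g.l"] = gloop_lift * unit(gl_centroid - cl_centroid)

    residues: list[Residue] = []
    filler_cursor = 0
    for col in range(1, len(cons) + 1):
        slot = slot_of_col.get(col)
        seqid = seqid_start + col - 1
        if slot is not None:
            if slot in delete_slots:
                continue
            aa1 = subs.get(slot, cons[col - 1]).upper()
            aa3 = AA3[aa1]
            region = table.region_of(slot)
            first = table.slots_in_region(region)[0]
            _, seg_dir = REGION_SEGMENTS[region]
            t = unit(np.asarray(seg_dir, float))
            ca = region_ca(table, slot) + shift.get(region, 0.0)
            parity = slot - first
            atoms = [(n_, p) for n_, p in _backbone(ca, t, parity)]
            d, u = _sidechain_frame(ca, t, slot, dfg, region, inward_slots)
            atoms.extend(build_sidechain(aa3, ca, d, u))
            if slot in trunc:
                keep = set(trunc[slot])
                atoms = [(n_, p) for n_, p in atoms if n_ in keep]
        else:
            aa3 = AA3[cons[col - 1]]
            ca = _FILLER_BASE + np.array([0.0, 4.2 * filler_cursor, 0.0])
            filler_cursor += 1
            t = np.array([0.0, 1.0, 0.0])
            atoms = [(n_, p) for n_, p in _backbone(ca, t, filler_cursor)]
            atoms.extend(build_sidechain(aa3, ca, np.array([0.0, 0.0, 1.0]),
                                         np.array([1.0, 0.0, 0.0])))
        residues.append(Residue(aa3, seqid,
                                [make_atom(n_, p) for n_, p in atoms]))
    return Monomer(source_id=source_id, model_index=1, chain_id=chain_id,
                   residues=residues)


def pocket_of_domain(monomer: Monomer, table: RegionTable | None = None) -> PocketAlignment:
    """Direct slot mapping for scaffold-built domains (no alignment step):
    residues carry seqids ``seqid_start + master_column - 1``."""
    table = table or load_region_table()
    seqid_start = min(r.seqid for r in monomer.residues) if monomer.residues else 101
    by_seqid = {r.seqid: r for r in monomer.residues}
    slots = []
    for index in range(1, N_SLOTS + 1):
        res = by_seqid.get(seqid_start + table.column_of(index) - 1)
        if res is None:
            slots.append(PocketSlot(index, table.region_of(index), GAP, None, None))
        else:
            expected = expected_heavy_atoms(res.name)
            missing = tuple(a for a in expected if not res.has_atom(a))
            slots.append(PocketSlot(index, table.region_of(index), res.one_letter,
                                    res.seqid, res, missing_atoms=missing))
    return PocketAlignment(kinase_id=monomer.source_id, slots=slots)


@lru_cache(maxsize=1)
def master_frame() -> Monomer:
    """The canonical master structural frame (DFG-in, noise-free)."""
    return build_domain(source_id="master_frame")


@lru_cache(maxsize=1)
def master_pocket() -> PocketAlignment:
    return pocket_of_domain(master_frame())
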