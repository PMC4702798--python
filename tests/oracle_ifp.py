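"""Independent brute-force interaction checker used as the IFP oracle.

Re-implements the seven geometric interaction rules with plain Python
loops and independent geometry (Newell plane normals, explicit vector
math) so that the package's vectorized detector can be verified
bit-for-bit against it.
"""

from __future__ import annotations

import math

from kinpocket.config import DEFAULT_CONFIG
from kinpocket.residues import (APOLAR_ATOMS, AROMATIC_RINGS, CHARGE_CENTERS,
                                SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS)

CFG = DEFAULT_CONFIG.interactions


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _sub(a, b):
    return [x - y for x, y in zip(a, b)]


def _dot(a, b):
    return sum(x * y for x, y in zip(a, b))


def _norm(a):
    return math.sqrt(_dot(a, a))


def _angle_deg(a, b, c):
    v1, v2 = _sub(a, b), _sub(c, b)
    n1, n2 = _norm(v1), _norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosv = max(-1.0, min(1.0, _dot(v1, v2) / (n1 * n2)))
    return math.degrees(math.acos(cosv))


def _newell_normal(points):
    nx = ny = nz = 0.0
    n = len(points)
    for i in range(n):
        x1, y1, z1 = points[i]
        x2, y2, z2 = points[(i + 1) % n]
        nx += (y1 - y2) * (z1 + z2)
        ny += (z1 - z2) * (x1 + x2)
        nz += (x1 - x2) * (y1 + y2)
    length = math.sqrt(nx * nx + ny * ny + nz * nz)
    return (nx / length, ny / length, nz / length)


def _centroid(points):
    n = len(points)
    return tuple(sum(p[k] for p in points) / n for k in range(3))


def _ligand_typing(record):
    """Independent ligand site extraction via explicit RDKit queries."""
    mol = record.mol
    conf = mol.GetConformer()
    pos = {i: tuple(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())}
    apolar = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "S":
            apolar.append(pos[atom.GetIdx()])
        elif sym == "C" and all(nb.GetSymbol() not in ("N", "O", "F")
                                for nb in atom.GetNeighbors()):
            apolar.append(pos[atom.GetIdx()])
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            pts = [pos[i] for i in ring]
            rings.append((_centroid(pts), _newell_normal(pts)))
    donors = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in ("N", "O") and atom.GetTotalNumHs() >= 1:
            ante = [pos[nb.GetIdx()] for nb in atom.GetNeighbors()
                    if nb.GetAtomicNum() > 1]
            donors.append((pos[atom.GetIdx()], ante))
    acceptors = []
    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() > 0:
            continue
        if atom.GetSymbol() == "O" or (atom.GetSymbol() == "N"
                                       and atom.GetTotalNumHs() == 0):
            acceptors.append(pos[atom.GetIdx()])
    charges = [(tuple(p), s) for p, s in record.charge_centers()]
    return apolar, rings, donors, acceptors, charges


def _residue_typing(residue, prev_c):
    name = residue.name
    get = lambda a: tuple(residue.coord(a)) if residue.has_atom(a) else None
    apolar = [get(a) for a in APOLAR_ATOMS.get(name, ()) if get(a)]
    rings = []
    for cycle in AROMATIC_RINGS.get(name, ()):
        pts = [get(a) for a in cycle]
        if all(p is not None for p in pts):
            rings.append((_centroid(pts), _newell_normal(pts)))
    donors = []
    if name != "PRO" and get("N") is not None:
        ante = [p for p in (get("CA"),
                            tuple(prev_c) if prev_c is not None else None)
                if p is not None]
        donors.append((get("N"), ante))
    for dn, antes in SIDECHAIN_DONORS.get(name, {}).items():
        if get(dn) is not None:
            donors.append((get(dn), [get(a) for a in antes if get(a)]))
    acceptors = [p for p in [get("O")] if p is not None]
    acceptors += [get(a) for a in SIDECHAIN_ACCEPTORS.get(name, ()) if get(a)]
    charges = [(get(a), s) for a, s in CHARGE_CENTERS.get(name, ())
               if get(a) is not None]
    return apolar, rings, donors, acceptors, charges


def _hbond_bit(donors, acceptors):
    for dpos, antes in donors:
        for acc in acceptors:
            if _dist(dpos, acc) > CFG.hbond_max:
                continue
            if not antes:
                return 1
            if any(_angle_deg(a, dpos, acc) >= CFG.hbond_donor_angle_min
                   for a in antes):
                return 1
    return 0


def brute_force_block(residue, prev_c, ligand_record):
    """Seven-bit block for one residue computed the slow, obvious way."""
    p_ap, p_rg, p_dn, p_ac, p_ch = _residue_typing(residue, prev_c)
    l_ap, l_rg, l_dn, l_ac, l_ch = _ligand_typing(ligand_record)
    bits = [0] * 7
    for a in p_ap:
        for b in l_ap:
            if _dist(a, b) <= CFG.hydrophobic_max:
                bits[0] = 1
    for (pc, pn) in p_rg:
        for (lc, ln) in l_rg:
            d = _dist(pc, lc)
            cosv = abs(max(-1.0, min(1.0, _dot(pn, ln))))
            ang = math.degrees(math.acos(cosv))
            if d <= CFG.aromatic_f2f_max and ang <= CFG.aromatic_f2f_angle_max:
                bits[1] = 1
            lo, hi = CFG.aromatic_e2f_angle_range
            if d <= CFG.aromatic_e2f_max and lo <= ang <= hi:
                bits[2] = 1
    bits[3] = _hbond_bit(p_dn, l_ac)
    bits[4] = _hbond_bit(l_dn, p_ac)
    for pp, ps in p_ch:
        for lp, ls in l_ch:
            if ps * ls < 0 and _dist(pp, tuple(lp)) <= CFG.ionic_max:
                if ps > 0:
                    bits[5] = 1
                else:
                    bits[6] = 1
    return bits


def brute_force_ifp(pocket, ligand_record):
    """Full 595-bit fingerprint via the brute-force checker."""
    seqids = {s.seqid: s.residue for s in pocket.slots if s.residue is not None}
    bits = []
    for slot in pocket.slots:
        if slot.is_gap:
            bits.extend([0] * 7)
            continue
        prev = seqids.get(slot.seqid - 1)
        prev_c = prev.coord("C") if prev is not None else None
        bits.extend(brute_force_block(slot.residue, prev_c, ligand_record))
    return bits
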