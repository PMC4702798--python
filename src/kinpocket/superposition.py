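"""Anchor-based superposition onto the master frame and the quality score.

Every structure is placed into the master coordinate frame by a
least-squares rigid fit of the backbone atoms of the anchor regions —
catalytic loop, DFG motif and hinge — onto their master counterparts.
Conformational descriptors, subpocket probes and water clusters are all
defined in that frame, so the fit is the coordinate backbone of the whole
annotation stage.  The per-structure quality score (0 bad .. 10 flawless)
summarizes how well the pocket superposes and how complete it is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, QualityConfig
from .errors import InputError, InsufficientAnchorsError
from .geometry import apply_rigid, kabsch, rmsd
from .model import Monomer
from .pocket_mapping import PocketAlignment
from .residues import BACKBONE

_BACKBONE_SET = tuple(BACKBONE)


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform onto the master frame plus fit statistics.

    ``rotation`` / ``translation`` map monomer coordinates into the master
    frame as ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd_anchor: float
    rmsd_pocket: float
    n_anchor_residues: int
    n_pocket_residues: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return apply_rigid(coords, self.rotation, self.translation)

    def transform_monomer(self, monomer: Monomer) -> Monomer:
        return monomer.transformed(self.rotation, self.translation)


def _paired_backbone(pocket: PocketAlignment, reference: PocketAlignment,
                     slots: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray, int]:
    mob, ref = [], []
    n_res = 0
    for idx in slots:
        s, r = pocket.slot(idx), reference.slot(idx)
        if s.is_gap or r.is_gap:
            continue
        pair = [(s.residue.coord(a), r.residue.coord(a)) for a in _BACKBONE_SET
                if s.residue.has_atom(a) and r.residue.has_atom(a)]
        if not pair:
            continue
        n_res += 1
        mob.extend(p[0] for p in pair)
        ref.extend(p[1] for p in pair)
    if not mob:
        return np.empty((0, 3)), np.empty((0, 3)), 0
    return np.array(mob), np.array(ref), n_res


def superpose(pocket: PocketAlignment, master: PocketAlignment | None = None,
              min_anchors: int = 3) -> SuperpositionResult:
    """Superpose a pocket onto the master frame.

    The fit uses backbone atoms (N, Ca, C, O) of the anchor slots
    (catalytic loop, xDFG, hinge); slots gapped on either side are
    skipped.  ``rmsd_pocket`` is evaluated over the backbone of all
    mapped slots after applying the anchor-fitted transform.
    """
    if master is None:
        from .scaffold import master_pocket
        master = master_pocket()
    from .pocket_mapping import load_region_table
    anchors = load_region_table().anchor_slots
    mob_a, ref_a, n_anchor = _paired_backbone(pocket, master, anchors)
    if n_anchor < min_anchors:
        raise InsufficientAnchorsError(
            f"only {n_anchor} anchor residues mapped (need >= {min_anchors})")
    r, t = kabsch(mob_a, ref_a)
    all_slots = tuple(range(1, len(pocket.slots) + 1))
    mob_p, ref_p, n_pocket = _paired_backbone(pocket, master, all_slots)
    return SuperpositionResult(
        rotation=r, translation=t,
        rmsd_anchor=rmsd(apply_rigid(mob_a, r, t), ref_a),
        rmsd_pocket=rmsd(apply_rigid(mob_p, r, t), ref_p),
        n_anchor_residues=n_anchor, n_pocket_residues=n_pocket,
    )


@dataclass(frozen=True)
class QualityScore:
    """Composite structure-quality estimate in [0, 10].

    10 means a flawless pocket: anchor and pocket RMSD within their
    penalty-free offsets, no missing residues, no missing atoms.  The
    score decreases linearly with each defect and is clamped at 0.
    """

    score: float
    anchor_term: float
    pocket_term: float
    missing_residue_term: float
    missing_atom_term: float


def compute_quality_score(rmsd_anchor: float, rmsd_pocket: float,
                          n_missing_residues: int, n_missing_atoms: int,
                          cfg: QualityConfig | None = None) -> QualityScore:
    """Linear-penalty quality score.

    score = clamp(10 - w1*max(0, rmsd_anchor - r0) - w2*max(0, rmsd_pocket - r1)
                     - w3*n_missing_residues - w4*n_missing_atoms, 0, 10)
    """
    cfg = cfg or DEFAULT_CONFIG.quality
    if min(rmsd_anchor, rmsd_pocket, n_missing_residues, n_missing_atoms) < 0:
        raise InputError("quality-score inputs must be non-negative")
    anchor_term = cfg.w_rmsd_anchor * max(0.0, rmsd_anchor - cfg.rmsd_anchor_offset)
    pocket_term = cfg.w_rmsd_pocket * max(0.0, rmsd_pocket - cfg.rmsd_pocket_offset)
    res_term = cfg.w_missing_residue * n_missing_residues
    atom_term = cfg.w_missing_atom * n_missing_atoms
    raw = 10.0 - anchor_term - pocket_term - res_term - atom_term
    return QualityScore(score=float(np.clip(raw, 0.0, 10.0)),
                        anchor_term=anchor_term, pocket_term=pocket_term,
                        missing_residue_term=res_term, missing_atom_term=atom_term)


def quality_for(pocket: PocketAlignment, sup: SuperpositionResult,
                cfg: QualityConfig | None = None) -> QualityScore:
    return compute_quality_score(sup.rmsd_anchor, sup.rmsd_pocket,
                                 pocket.n_gaps, pocket.n_missing_atoms, cfg)
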