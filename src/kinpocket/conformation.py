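"""DFG / aC-helix / G-rich-loop conformation annotation.

The activation-state descriptors follow the classic structural reading of
the kinase fold: the DFG motif flips between the active DFG-in state and
the inactive DFG-out state (with an intermediate DFG-outlike), the
aC-helix swings in and out (measured by the Ca distance between the xDFG
phenylalanine and the aC glutamate), and the G-rich loop flexes over the
ATP site.  DFG classification uses three descriptors — the accessible
surface area of the xDFG aspartate and the y-components of the
(Cgamma - Calpha) vectors of the xDFG aspartate and phenylalanine in the
master frame — fed to a shallow decision tree whose thresholds were
fitted on a labeled corpus and frozen into a versioned JSON model file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .config import ConformationConfig, DEFAULT_CONFIG
from .errors import InputError, UndefinedDescriptorError
from .geometry import dihedral_about_axis, principal_axis
from .pocket_mapping import (ALPHA_C_GLU, PocketAlignment, XDFG_D, XDFG_F,
                             load_region_table)
from .residues import BACKBONE, vdw_radius

DFG_CLASSES = ("DFG-in", "DFG-out", "DFG-outlike")
ALPHA_C_CLASSES = ("aC-in", "aC-outlike", "aC-out")


# ---------------------------------------------------------------------------
# Accessible surface area (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (Fibonacci
    lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def shrake_rupley(coords: np.ndarray, elements: list[str],
                  probe_radius: float = 1.4, n_points: int = 960,
                  indices: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Each atom's solvent sphere (vdW + probe radius) is sampled with a
    deterministic spherical lattice; a point is accessible when it lies
    outside every neighbouring atom's solvent sphere.  ``indices``
    restricts which atoms' areas are computed (occlusion still uses the
    full atom set); other entries of the returned array stay zero.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InputError("coords must be (n, 3)")
    radii = np.array([vdw_radius(e) for e in elements]) + probe_radius
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    out = np.zeros(len(coords))
    todo = range(len(coords)) if indices is None else np.asarray(indices, int)
    for i in todo:
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                      if j != i]
        sphere = coords[i] + radii[i] * pts
        if neighbours:
            nb = np.array(neighbours)
            d2 = ((sphere[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            accessible = (d2 > (radii[nb] ** 2)[None, :]).all(axis=1)
        else:
            accessible = np.ones(len(sphere), bool)
        out[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return out


def accessible_surface_area(pocket: PocketAlignment, index: int,
                            cfg: ConformationConfig | None = None) -> float:
    """ASA of one pocket residue in the context of all pocket residues."""
    cfg = cfg or DEFAULT_CONFIG.conformation
    slot = pocket.slot(index)
    if slot.is_gap:
        raise UndefinedDescriptorError(f"slot {index} is a gap")
    coords, elements, target = [], [], []
    for s in pocket.slots:
        if s.is_gap:
            continue
        for a in s.residue.atoms:
            if a.element.upper() == "H":
                continue
            if s.index == index:
                target.append(len(coords))
            coords.append(a.pos)
            elements.append(a.element)
    asa = shrake_rupley(np.array(coords), elements,
                        probe_radius=cfg.asa_probe_radius,
                        n_points=cfg.asa_sphere_points,
                        indices=np.array(target, int))
    return float(asa[target].sum())


# ---------------------------------------------------------------------------
# DFG descriptors and decision tree

def dfg_vectors(pocket: PocketAlignment) -> tuple[float, float]:
    """y-components of the (Cgamma - Calpha) vectors of the xDFG aspartate
    (slot 81) and phenylalanine (slot 82), master-frame convention.

    The pocket must already be superposed onto the master frame.
    """
    out = []
    for idx in (XDFG_D, XDFG_F):
        slot = pocket.slot(idx)
        if slot.is_gap:
            raise UndefinedDescriptorError(f"slot {idx} is a gap")
        ca, cg = slot.residue.coord("CA"), slot.residue.coord("CG")
        if ca is None or cg is None:
            raise UndefinedDescriptorError(f"slot {idx} lacks CA/CG")
        out.append(float((cg - ca)[1]))
    return out[0], out[1]


def dfg_descriptors(pocket: PocketAlignment,
                    cfg: ConformationConfig | None = None) -> dict[str, float]:
    yd, yf = dfg_vectors(pocket)
    return {"asa_d81": accessible_surface_area(pocket, XDFG_D, cfg),
            "yd": yd, "yf": yf}


_FEATURES = ("asa_d81", "yd", "yf")


@dataclass(frozen=True)
class DecisionTreeModel:
    """Frozen axis-aligned decision tree (JSON-serializable).

    Nodes are dicts: leaves carry {"class": label}; internal nodes carry
    {"feature", "threshold", "left", "right"} with the left branch taken
    when feature value <= threshold.
    """

    root: dict

    def predict(self, descriptors: dict[str, float]) -> str:
        node = self.root
        while "class" not in node:
            value = descriptors[node["feature"]]
            node = node["left"] if value <= node["threshold"] else node["right"]
        return node["class"]

    def to_json(self) -> str:
        return json.dumps({"features": _FEATURES, "tree": self.root}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTreeModel":
        return cls(root=json.loads(text)["tree"])


@lru_cache(maxsize=1)
def default_dfg_tree() -> DecisionTreeModel:
    text = resources.files("kinpocket.data").joinpath("dfg_tree.json").read_text()
    return DecisionTreeModel.from_json(text)


def classify_dfg(descriptors: dict[str, float] | None,
                 tree: DecisionTreeModel | None = None) -> str:
    """Apply the (frozen) decision tree; undefined descriptors yield
    "unknown"."""
    if descriptors is None:
        return "unknown"
    tree = tree or default_dfg_tree()
    try:
        return tree.predict(descriptors)
    except KeyError as exc:
        raise InputError(f"descriptor missing: {exc}") from exc


def train_dfg_tree(descriptor_rows: list[dict[str, float]], labels: list[str],
                   max_depth: int = 3, n_folds: int = 10,
                   seed: int = 0) -> tuple[DecisionTreeModel, float]:
    """CART training harness with stratified k-fold cross-validation.

    Returns the tree fitted on all data plus the mean CV accuracy; the
    caller freezes the returned model to JSON for reproducible use.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.tree import DecisionTreeClassifier

    x = np.array([[row[f] for f in _FEATURES] for row in descriptor_rows])
    y = np.array(labels)
    clf = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accuracy = float(cross_val_score(clf, x, y, cv=cv).mean())
    clf.fit(x, y)

    t = clf.tree_
    classes = clf.classes_

    def node_to_dict(i: int) -> dict:
        if t.children_left[i] == -1:
            return {"class": str(classes[int(np.argmax(t.value[i]))])}
        return {"feature": _FEATURES[t.feature[i]],
                "threshold": round(float(t.threshold[i]), 4),
                "left": node_to_dict(t.children_left[i]),
                "right": node_to_dict(t.children_right[i])}

    return DecisionTreeModel(root=node_to_dict(0)), accuracy


# ---------------------------------------------------------------------------
# aC-helix classification

def alpha_c_distance(pocket: PocketAlignment) -> float:
    """|Ca(F.xDFG.82) - Ca(E.aC.24)| in angstroms."""
    f, e = pocket.slot(XDFG_F), pocket.slot(ALPHA_C_GLU)
    for slot in (f, e):
        if slot.is_gap or not slot.residue.has_atom("CA"):
            raise UndefinedDescriptorError(f"slot {slot.index} missing Ca")
    return float(np.linalg.norm(f.residue.coord("CA") - e.residue.coord("CA")))


def classify_alpha_c(pocket: PocketAlignment,
                     cfg: ConformationConfig | None = None) -> str:
    """Three-class aC position from the F82-E24 Ca distance:
    d <= t1 -> aC-in; t1 < d <= t2 -> aC-outlike; d > t2 -> aC-out."""
    cfg = cfg or DEFAULT_CONFIG.conformation
    try:
        d = alpha_c_distance(pocket)
    except UndefinedDescriptorError:
        return "unknown"
    eps = 1e-9          # inclusive boundaries despite float round-off
    if d <= cfg.alpha_c_in_max + eps:
        return "aC-in"
    if d <= cfg.alpha_c_outlike_max + eps:
        return "aC-outlike"
    return "aC-out"


# ---------------------------------------------------------------------------
# G-rich loop descriptors

def _region_backbone(pocket: PocketAlignment, region: str) -> np.ndarray:
    table = load_region_table()
    coords = []
    for idx in table.slots_in_region(region):
        slot = pocket.slot(idx)
        if slot.is_gap:
            continue
        coords.extend(slot.residue.coord(a) for a in BACKBONE
                      if slot.residue.has_atom(a))
    if not coords:
        raise UndefinedDescriptorError(f"region {region} fully unresolved")
    return np.array(coords)


def gloop_descriptors(pocket: PocketAlignment) -> tuple[float, float, float]:
    """(angle deg, distance A, rotation deg) of the G-rich loop.

    angle: planar angle G-loop-centroid - hinge-centroid - catalytic-loop
    centroid; distance: G-loop to catalytic-loop centroid separation;
    rotation: dihedral between the two loops' principal axes about the
    centroid-centroid axis.  Centroids/axes use backbone atoms.
    """
    gl = _region_backbone(pocket, "g.l")
    hinge = _region_backbone(pocket, "hinge")
    cl = _region_backbone(pocket, "c.l")
    g_c, h_c, c_c = gl.mean(axis=0), hinge.mean(axis=0), cl.mean(axis=0)
    v1, v2 = g_c - h_c, c_c - h_c
    angle = float(np.degrees(np.arccos(np.clip(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))))
    distance = float(np.linalg.norm(g_c - c_c))
    axis = g_c - c_c
    rot = dihedral_about_axis(principal_axis(gl), principal_axis(cl), axis)
    return angle, distance, float(rot)


# ---------------------------------------------------------------------------
# Bundled annotation

@dataclass(frozen=True)
class ConformationAnnotation:
    """DFG/aC/G-loop classes plus the raw descriptors that produced them."""

    dfg: str
    alpha_c: str
    gloop: tuple[float, float, float] | None
    asa_d81: float | None
    yd: float | None
    yf: float | None
    d_f82_e24: float | None


def annotate_conformation(pocket: PocketAlignment,
                          cfg: ConformationConfig | None = None,
                          tree: DecisionTreeModel | None = None) -> ConformationAnnotation:
    """Full conformational annotation of a master-frame-superposed pocket;
    descriptors that cannot be computed yield class "unknown"."""
    cfg = cfg or DEFAULT_CONFIG.conformation
    try:
        desc = dfg_descriptors(pocket, cfg)
        dfg = classify_dfg(desc, tree)
    except UndefinedDescriptorError:
        desc, dfg = None, "unknown"
    alpha_c = classify_alpha_c(pocket, cfg)
    try:
        d_ac = alpha_c_distance(pocket)
    except UndefinedDescriptorError:
        d_ac = None
    try:
        gloop = gloop_descriptors(pocket)
    except UndefinedDescriptorError:
        gloop = None
    return ConformationAnnotation(
        dfg=dfg, alpha_c=alpha_c, gloop=gloop,
        asa_d81=desc["asa_d81"] if desc else None,
        yd=desc["yd"] if desc else None,
        yf=desc["yf"] if desc else None,
        d_f82_e24=d_ac)
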