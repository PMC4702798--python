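"""Probe-grid subpocket model and conserved water clusters.

Subpockets are described empirically: a 0.5 A grid of spatial probes is
laid over the envelope of master-frame-superposed ligands, each probe is
scored by its ratio of close contacts (< 1.0 A) with ligands annotated as
binding a given (sub)pocket versus ligands that do not, and the
best-discriminating probes are retained per label.  A new ligand is
flagged for a (sub)pocket when any heavy atom touches any of its probes.

Conserved pocket waters are handled analogously in the master frame: 13
cluster centroids (I1-I11 plus the two DFG-out-specific sites O1/O2) are
derived by average-linkage clustering of observed waters; each structure's
waters are assigned to the nearest centroid within an assignment radius
and their H-bond pattern with ligand and protein is evaluated with the
fingerprint module's geometric rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .config import DEFAULT_CONFIG, SubpocketConfig, WaterConfig
from .errors import InputError
from .fingerprint import _hbond, ligand_sites, residue_sites
from .ligands import LigandRecord
from .pocket_mapping import PocketAlignment

MAJOR_LABELS = ("front_cleft", "gate_area", "back_cleft")
SUBPOCKET_LABELS = ("FP-I", "FP-II", "BP-I-A", "BP-I-B", "BP-II-in",
                    "BP-II-A-in", "BP-II-B-in", "BP-II-out", "BP-II-B",
                    "BP-III", "BP-IV", "BP-V")
WATER_LABELS = ("I1", "I2", "I3", "I4", "I5", "I6", "I7", "I8", "I9",
                "I10", "I11", "O1", "O2")
DFG_OUT_WATER_LABELS = ("O1", "O2")


def major_of(label: str) -> str | None:
    """Major region containing a subpocket label (None for majors)."""
    if label in MAJOR_LABELS:
        return None
    if label.startswith("FP"):
        return "front_cleft"
    if label.startswith("BP-I-"):
        return "gate_area"
    return "back_cleft"


# ---------------------------------------------------------------------------
# Subpocket model

@dataclass
class SubpocketModel:
    """Retained probe points per (sub)pocket label, master frame."""

    probes: dict[str, np.ndarray]
    grid_spacing: float
    contact_radius: float
    provenance: dict = field(default_factory=dict)

    def labels(self) -> tuple[str, ...]:
        return tuple(self.probes)

    def n_probes(self, label: str) -> int:
        return len(self.probes.get(label, ()))

    def save(self, directory: str | Path) -> None:
        from .mol2 import points_to_mol2
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"grid_spacing": self.grid_spacing,
                "contact_radius": self.contact_radius,
                "provenance": self.provenance,
                "labels": {}}
        for label, pts in self.probes.items():
            fname = f"probes_{label.replace('-', '_')}.mol2"
            (directory / fname).write_text(points_to_mol2(pts, label))
            meta["labels"][label] = fname
        (directory / "subpocket_model.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "SubpocketModel":
        directory = Path(directory)
        meta = json.loads((directory / "subpocket_model.json").read_text())
        probes = {}
        for label, fname in meta["labels"].items():
            pts = []
            in_atoms = False
            for line in (directory / fname).read_text().splitlines():
                if line.startswith("@<TRIPOS>ATOM"):
                    in_atoms = True
                    continue
                if line.startswith("@<TRIPOS>"):
                    in_atoms = False
                    continue
                if in_atoms and line.strip():
                    parts = line.split()
                    pts.append([float(parts[2]), float(parts[3]), float(parts[4])])
            probes[label] = np.array(pts) if pts else np.empty((0, 3))
        return cls(probes=probes, grid_spacing=meta["grid_spacing"],
                   contact_radius=meta["contact_radius"],
                   provenance=meta.get("provenance", {}))


def _grid_origin() -> np.ndarray:
    """Grid anchored to the master-frame centroid of the hinge backbone,
    for reproducibility of probe coordinates."""
    from .scaffold import master_pocket
    from .pocket_mapping import load_region_table
    from .residues import BACKBONE
    pk = master_pocket()
    coords = []
    for idx in load_region_table().slots_in_region("hinge"):
        res = pk.slot(idx).residue
        coords.extend(res.coord(a) for a in BACKBONE if res.has_atom(a))
    return np.asarray(coords).mean(axis=0)


def train_subpocket_model(training: list[tuple[np.ndarray, set[str]]],
                          cfg: SubpocketConfig | None = None,
                          min_positive_contacts: int = 3) -> SubpocketModel:
    """Fit probe sets from (ligand atom cloud, label set) examples.

    Probes are grid points (spacing ``grid_spacing``, origin anchored to
    the master hinge centroid) scored per label by close contacts
    (< ``contact_radius``) with ligands that bind the (sub)pocket versus
    ligands that do not; contacts are counted per distinct ligand so a
    single molecule cannot dominate a probe.  Probes with contact ratio
    >= ``min_ratio`` and at least ``min_positive_contacts`` positive
    ligands are kept, best ``top_k`` first.  Labels without a positive
    and a negative example are skipped.
    """
    cfg = cfg or DEFAULT_CONFIG.subpockets
    if not training:
        raise InputError("empty training set")
    all_labels = [lab for lab in (*MAJOR_LABELS, *SUBPOCKET_LABELS)
                  if any(lab in labs for _, labs in training)]
    extra = sorted({lab for _, labs in training for lab in labs}
                   - set(MAJOR_LABELS) - set(SUBPOCKET_LABELS))
    all_labels += extra

    origin = _grid_origin()
    all_coords = np.vstack([c for c, _ in training])
    lo = np.floor((all_coords.min(axis=0) - cfg.envelope_padding - origin)
                  / cfg.grid_spacing).astype(int)
    hi = np.ceil((all_coords.max(axis=0) + cfg.envelope_padding - origin)
                 / cfg.grid_spacing).astype(int)
    axes = [origin[k] + cfg.grid_spacing * np.arange(lo[k], hi[k] + 1)
            for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    # keep only grid points near any ligand atom at all
    tree_all = cKDTree(all_coords)
    near = tree_all.query_ball_point(grid, cfg.contact_radius)
    occupied = np.array([len(n) > 0 for n in near])
    grid = grid[occupied]
    grid_tree = cKDTree(grid)

    probes: dict[str, np.ndarray] = {}
    for label in all_labels:
        pos = [c for c, labs in training if label in labs]
        neg = [c for c, labs in training if label not in labs]
        if not pos or not neg:
            warnings.warn(f"label {label!r} lacks positives or negatives; skipped")
            continue
        pos_counts = np.zeros(len(grid))
        neg_counts = np.zeros(len(grid))
        for cloud in pos:
            hit = np.zeros(len(grid), bool)
            for i, hits in enumerate(grid_tree.query_ball_tree(
                    cKDTree(cloud), cfg.contact_radius)):
                hit[i] = bool(hits)
            pos_counts += hit
        for cloud in neg:
            hit = np.zeros(len(grid), bool)
            for i, hits in enumerate(grid_tree.query_ball_tree(
                    cKDTree(cloud), cfg.contact_radius)):
                hit[i] = bool(hits)
            neg_counts += hit
        with np.errstate(divide="ignore"):
            ratio = np.where(neg_counts > 0, pos_counts / np.maximum(neg_counts, 1e-9),
                             np.inf)
        keep = (pos_counts >= min_positive_contacts) & (ratio >= cfg.min_ratio)
        idx = np.flatnonzero(keep)
        order = np.lexsort((idx, -pos_counts[idx],
                            -np.where(np.isinf(ratio[idx]), 1e9, ratio[idx])))
        idx = idx[order][:cfg.top_k]
        probes[label] = grid[np.sort(idx)]
    return SubpocketModel(probes=probes, grid_spacing=cfg.grid_spacing,
                          contact_radius=cfg.contact_radius,
                          provenance={"n_training": len(training),
                                      "min_ratio": cfg.min_ratio,
                                      "top_k": cfg.top_k})


def assign_subpockets(ligand_coords: np.ndarray,
                      model: SubpocketModel) -> dict[str, bool]:
    """Flag each (sub)pocket label whose probe set is touched by any
    ligand heavy atom; subpocket flags propagate to their major region."""
    if not model.probes:
        raise InputError("empty subpocket model")
    ligand_coords = np.asarray(ligand_coords, float)
    if ligand_coords.ndim != 2 or ligand_coords.shape[1] != 3:
        raise InputError("ligand coordinates must be (n, 3)")
    tree = cKDTree(ligand_coords)
    flags: dict[str, bool] = {}
    for label, pts in model.probes.items():
        if len(pts) == 0:
            flags[label] = False
            continue
        hits = tree.query_ball_point(pts, model.contact_radius)
        flags[label] = any(len(h) > 0 for h in hits)
    # hierarchy: any subpocket implies its major region
    for label, val in list(flags.items()):
        if val:
            maj = major_of(label)
            if maj is not None:
                flags[maj] = True
    return flags


@lru_cache(maxsize=4)
def default_subpocket_model(seed: int = 1, n_training: int = 120) -> SubpocketModel:
    """Deterministic model trained on the bundled synthetic ligand corpus."""
    from .fixtures import generate_subpocket_corpus
    corpus = generate_subpocket_corpus(n_training, seed=seed)
    model = train_subpocket_model(corpus)
    model.provenance["corpus_seed"] = seed
    return model


# ---------------------------------------------------------------------------
# Water clusters

@dataclass(frozen=True)
class WaterClusterSet:
    """13 labeled water-cluster centroids in the master frame."""

    centroids: dict[str, tuple[float, float, float]]
    assignment_radius: float
    dfg_out_specific: tuple[str, ...] = DFG_OUT_WATER_LABELS

    def __post_init__(self):
        if len(self.centroids) != 13:
            raise InputError("water cluster set must hold exactly 13 centroids")

    def to_json(self) -> str:
        return json.dumps({"assignment_radius": self.assignment_radius,
                           "dfg_out_specific": list(self.dfg_out_specific),
                           "centroids": {k: list(v) for k, v in
                                         self.centroids.items()}}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "WaterClusterSet":
        data = json.loads(text)
        return cls(centroids={k: tuple(v) for k, v in data["centroids"].items()},
                   assignment_radius=data["assignment_radius"],
                   dfg_out_specific=tuple(data["dfg_out_specific"]))


@lru_cache(maxsize=1)
def default_water_clusters() -> WaterClusterSet:
    text = resources.files("kinpocket.data").joinpath("water_clusters.json").read_text()
    return WaterClusterSet.from_json(text)


def derive_water_clusters(observations: list[tuple[np.ndarray, str]],
                          cfg: WaterConfig | None = None,
                          out_fraction: float = 0.9,
                          reference_labels: dict[str, tuple[float, float, float]]
                          | None = None) -> WaterClusterSet:
    """Average-linkage clustering of observed waters into 13 clusters.

    ``observations`` pairs each structure's master-frame water coordinates
    with its DFG class.  Clusters whose members come (almost) exclusively
    from DFG-out structures are labeled O1/O2; the remaining clusters are
    labeled I1..I11.  Labels are assigned deterministically by descending
    cluster size (ties by centroid coordinates); when ``reference_labels``
    maps existing labels to centroids (e.g. a previous release of the
    cluster file), each cluster instead inherits the label of the nearest
    reference centroid, keeping names stable across re-derivations.
    """
    cfg = cfg or DEFAULT_CONFIG.waters
    coords = np.vstack([c for c, _ in observations])
    is_out = np.concatenate([np.full(len(c), lab == "DFG-out")
                             for c, lab in observations])
    if len(coords) < 13:
        raise InputError("need at least 13 water observations")
    z = linkage(coords, method="average")
    assignment = fcluster(z, t=13, criterion="maxclust")
    clusters = []
    for cid in np.unique(assignment):
        mask = assignment == cid
        clusters.append({"centroid": coords[mask].mean(axis=0),
                         "size": int(mask.sum()),
                         "out_frac": float(is_out[mask].mean())})
    out_like = sorted(clusters, key=lambda c: (-c["out_frac"], -c["size"]))[:2]
    out_ids = {id(c) for c in out_like if c["out_frac"] >= out_fraction}
    inner = [c for c in clusters if id(c) not in out_ids]
    outer = [c for c in clusters if id(c) in out_ids]
    while len(outer) < 2:          # degenerate corpora: fall back by fraction
        cand = max(inner, key=lambda c: (c["out_frac"], c["size"]))
        inner.remove(cand)
        outer.append(cand)

    def sort_key(c):
        return (-c["size"], round(c["centroid"][0], 3),
                round(c["centroid"][1], 3), round(c["centroid"][2], 3))

    centroids: dict[str, tuple[float, float, float]] = {}
    if reference_labels is not None:
        ref_names = list(reference_labels)
        ref_pts = np.array([reference_labels[k] for k in ref_names])
        taken: set[str] = set()
        for c in sorted(inner + outer, key=sort_key):
            order = np.argsort(np.linalg.norm(ref_pts - c["centroid"], axis=1))
            name = next(ref_names[int(k)] for k in order
                        if ref_names[int(k)] not in taken)
            taken.add(name)
            centroids[name] = tuple(round(float(x), 3) for x in c["centroid"])
        centroids = {k: centroids[k] for k in ref_names if k in centroids}
    else:
        for i, c in enumerate(sorted(inner, key=sort_key), start=1):
            centroids[f"I{i}"] = tuple(round(float(x), 3) for x in c["centroid"])
        for i, c in enumerate(sorted(outer, key=sort_key), start=1):
            centroids[f"O{i}"] = tuple(round(float(x), 3) for x in c["centroid"])
    return WaterClusterSet(centroids=centroids,
                           assignment_radius=cfg.assignment_radius)


@dataclass(frozen=True)
class WaterAssignment:
    position: tuple[float, float, float]
    label: str
    hbond_ligand: bool
    hbond_protein: bool


def assign_water_clusters(water_coords: np.ndarray,
                          clusters: WaterClusterSet | None = None,
                          pocket: PocketAlignment | None = None,
                          ligand: LigandRecord | None = None,
                          ) -> list[WaterAssignment]:
    """Assign master-frame waters to the nearest centroid within the
    assignment radius (ties broken by label order; unassigned waters are
    dropped) and evaluate each kept water's H-bond pattern."""
    clusters = clusters or default_water_clusters()
    water_coords = np.asarray(water_coords, float)
    if water_coords.size == 0:
        return []
    labels = [l for l in WATER_LABELS if l in clusters.centroids]
    labels += [l for l in clusters.centroids if l not in labels]
    cents = np.array([clusters.centroids[l] for l in labels])
    lsites = ligand_sites(ligand) if ligand is not None else None
    rsites = None
    if pocket is not None:
        rsites = [residue_sites(s.residue) for s in pocket.slots if not s.is_gap]
    cfg = DEFAULT_CONFIG.interactions
    out: list[WaterAssignment] = []
    for w in water_coords:
        d = np.linalg.norm(cents - w, axis=1)
        best = int(np.argmin(d))     # argmin returns the first (lowest label)
        if d[best] > clusters.assignment_radius:
            continue
        water_donor = [(w, [])]      # no antecedents: distance-only donor
        hb_lig = False
        if lsites is not None:
            hb_lig = (_hbond(water_donor, lsites.acceptors, cfg)
                      or _hbond(lsites.donors, np.array([w]), cfg))
        hb_prot = False
        if rsites is not None:
            for rs in rsites:
                if (_hbond(water_donor, rs.acceptors, cfg)
                        or _hbond(rs.donors, np.array([w]), cfg)):
                    hb_prot = True
                    break
        out.append(WaterAssignment(position=tuple(round(float(x), 3) for x in w),
                                   label=labels[best],
                                   hbond_ligand=hb_lig, hbond_protein=hb_prot))
    return out
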