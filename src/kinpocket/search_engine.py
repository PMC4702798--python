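"""Query engine over annotated kinase-structure collections.

An :class:`AnnotationRecord` is the searchable unit: one processed
monomer with its pocket sequence, interaction fingerprint, conformation
classes, subpocket flags, water assignments, quality score and ligand
descriptors.  A :class:`Query` is a conjunction of optional clauses
(pocket composition, conformations, subpockets, waters, interaction
pattern, fingerprint similarity, ligand similarity/substructure,
physicochemical presets, quality/resolution bounds); results are ordered
by descending fingerprint similarity when a similarity clause is present,
otherwise by entry id.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

from .config import PROPERTY_PRESETS
from .errors import InputError, QueryError
from .fingerprint import InteractionFingerprint, InteractionPattern, ifp_similarity, match_pattern
from .pocket_mapping import N_SLOTS

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def ligand_descriptors(mol: Chem.Mol) -> dict[str, float]:
    """Standard physicochemical descriptors (logP is the Crippen
    atomic-contribution estimate)."""
    return {
        "mw": round(Descriptors.MolWt(mol), 3),
        "logp": round(Crippen.MolLogP(mol), 3),
        "hbd": int(Lipinski.NumHDonors(mol)),
        "hba": int(Lipinski.NumHAcceptors(mol)),
        "rotatable": int(Lipinski.NumRotatableBonds(mol)),
        "heavy_atoms": int(mol.GetNumHeavyAtoms()),
    }


@lru_cache(maxsize=256)
def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES {smiles!r}")
    return mol


def canonical_tautomer_smiles(smiles: str) -> str:
    """Canonical-tautomer SMILES used for (approximate) exact-ligand
    matching across tautomeric forms."""
    enum = rdMolStandardize.TautomerEnumerator()
    return Chem.MolToSmiles(enum.Canonicalize(_mol_from_smiles(smiles)))


def ligand_similarity(smiles_a: str, smiles_b: str, kind: str = "morgan") -> float:
    """Tanimoto similarity between two molecules using a circular
    (Morgan radius-2) or 166-key structural (MACCS) fingerprint."""
    ma, mb = _mol_from_smiles(smiles_a), _mol_from_smiles(smiles_b)
    if kind == "morgan":
        fa, fb = _MORGAN.GetFingerprint(ma), _MORGAN.GetFingerprint(mb)
    elif kind == "maccs":
        fa, fb = MACCSkeys.GenMACCSKeys(ma), MACCSkeys.GenMACCSKeys(mb)
    else:
        raise QueryError(f"unknown ligand fingerprint kind {kind!r}")
    return float(DataStructs.TanimotoSimilarity(fa, fb))


# ---------------------------------------------------------------------------
# Record

@dataclass
class AnnotationRecord:
    """One annotated monomer: the searchable unit.  Immutable by
    convention once built."""

    entry_id: str
    kinase: str = ""
    family: str = ""
    group: str = ""
    species: str = ""
    pocket_sequence: str = "-" * N_SLOTS
    gap_slots: tuple[int, ...] = ()
    mutations: tuple[tuple[int, str, str], ...] = ()
    ifp: InteractionFingerprint | None = None
    dfg: str = "unknown"
    alpha_c: str = "unknown"
    gloop: tuple[float, float, float] | None = None
    conformation_descriptors: dict = field(default_factory=dict)
    subpockets: dict[str, bool] = field(default_factory=dict)
    water_labels: tuple[str, ...] = ()
    water_hbonds: tuple[tuple[str, bool, bool], ...] = ()
    quality_score: float = 0.0
    rmsd_anchor: float = 0.0
    rmsd_pocket: float = 0.0
    resolution: float | None = None
    ligand_smiles: str | None = None
    ligand_properties: dict = field(default_factory=dict)

    def residue_at(self, index: int) -> str:
        if not 1 <= index <= N_SLOTS:
            raise InputError(f"slot index out of 1..{N_SLOTS}")
        return self.pocket_sequence[index - 1]

    # -- persistence (collection store: one JSON per record) --

    def to_json(self) -> str:
        data = {k: getattr(self, k) for k in (
            "entry_id", "kinase", "family", "group", "species",
            "pocket_sequence", "dfg", "alpha_c", "quality_score",
            "rmsd_anchor", "rmsd_pocket", "resolution", "ligand_smiles")}
        data["gap_slots"] = list(self.gap_slots)
        data["mutations"] = [list(m) for m in self.mutations]
        data["gloop"] = list(self.gloop) if self.gloop else None
        data["conformation_descriptors"] = self.conformation_descriptors
        data["subpockets"] = self.subpockets
        data["water_labels"] = list(self.water_labels)
        data["water_hbonds"] = [list(w) for w in self.water_hbonds]
        data["ligand_properties"] = self.ligand_properties
        if self.ifp is not None:
            data["ifp_hex"] = self.ifp.to_hex()
            data["ifp_apo"] = self.ifp.apo
        return json.dumps(data, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AnnotationRecord":
        d = json.loads(text)
        ifp = None
        if "ifp_hex" in d:
            ifp = InteractionFingerprint.from_hex(d.pop("ifp_hex"),
                                                  apo=d.pop("ifp_apo", False))
        return cls(
            entry_id=d["entry_id"], kinase=d.get("kinase", ""),
            family=d.get("family", ""), group=d.get("group", ""),
            species=d.get("species", ""),
            pocket_sequence=d.get("pocket_sequence", "-" * N_SLOTS),
            gap_slots=tuple(d.get("gap_slots", ())),
            mutations=tuple(tuple(m) for m in d.get("mutations", ())),
            ifp=ifp, dfg=d.get("dfg", "unknown"),
            alpha_c=d.get("alpha_c", "unknown"),
            gloop=tuple(d["gloop"]) if d.get("gloop") else None,
            conformation_descriptors=d.get("conformation_descriptors", {}),
            subpockets=d.get("subpockets", {}),
            water_labels=tuple(d.get("water_labels", ())),
            water_hbonds=tuple(tuple(w) for w in d.get("water_hbonds", ())),
            quality_score=d.get("quality_score", 0.0),
            rmsd_anchor=d.get("rmsd_anchor", 0.0),
            rmsd_pocket=d.get("rmsd_pocket", 0.0),
            resolution=d.get("resolution"),
            ligand_smiles=d.get("ligand_smiles"),
            ligand_properties=d.get("ligand_properties", {}))


def save_collection(records: list[AnnotationRecord], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in records:
        (directory / f"{rec.entry_id}.json").write_text(rec.to_json())


def load_collection(directory: str | Path) -> list[AnnotationRecord]:
    directory = Path(directory)
    return [AnnotationRecord.from_json(p.read_text())
            for p in sorted(directory.glob("*.json"))]


# ---------------------------------------------------------------------------
# Query

def property_preset(name: str) -> dict[str, tuple[float | None, float | None]]:
    """Descriptor range set for a named physicochemical preset."""
    try:
        return dict(PROPERTY_PRESETS[name])
    except KeyError:
        raise QueryError(f"unknown property preset {name!r}; known: "
                         f"{sorted(PROPERTY_PRESETS)}") from None


@dataclass
class Query:
    """Conjunction of optional clauses; an empty query matches everything."""

    pocket_composition: dict[int, str | set[str]] = field(default_factory=dict)
    dfg: tuple[str, ...] = ()
    alpha_c: tuple[str, ...] = ()
    subpockets_present: tuple[str, ...] = ()
    subpockets_absent: tuple[str, ...] = ()
    waters_present: tuple[str, ...] = ()
    waters_absent: tuple[str, ...] = ()
    interaction_pattern: InteractionPattern | None = None
    ifp_reference: InteractionFingerprint | None = None
    ifp_min_similarity: float | None = None
    ligand_reference: str | None = None          # SMILES
    ligand_fp_kind: str = "morgan"               # morgan | maccs
    ligand_min_similarity: float | None = None
    ligand_max_similarity: float | None = None
    substructure: str | None = None              # SMARTS or SMILES
    exact_ligand: str | None = None              # SMILES, tautomer-aware
    property_preset: str | None = None
    property_ranges: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict)
    min_quality: float | None = None
    max_resolution: float | None = None


def _check_ranges(props: dict, ranges: dict, entry: str) -> bool:
    for key, (lo, hi) in ranges.items():
        if key not in props:
            return False
        v = props[key]
        if lo is not None and v < lo:
            return False
        if hi is not None and v > hi:
            return False
    return True


def _matches(rec: AnnotationRecord, q: Query) -> tuple[bool, float | None]:
    for index, allowed in q.pocket_composition.items():
        if not 1 <= int(index) <= N_SLOTS:
            raise QueryError(f"pocket composition: slot {index} out of range")
        allowed_set = {allowed} if isinstance(allowed, str) else set(allowed)
        if rec.residue_at(int(index)) not in allowed_set:
            return False, None
    if q.dfg and rec.dfg not in q.dfg:
        return False, None
    if q.alpha_c and rec.alpha_c not in q.alpha_c:
        return False, None
    for label in q.subpockets_present:
        if not rec.subpockets.get(label, False):
            return False, None
    for label in q.subpockets_absent:
        if rec.subpockets.get(label, False):
            return False, None
    for label in q.waters_present:
        if label not in rec.water_labels:
            return False, None
    for label in q.waters_absent:
        if label in rec.water_labels:
            return False, None
    if q.interaction_pattern is not None:
        if rec.ifp is None or not match_pattern(rec.ifp, q.interaction_pattern):
            return False, None
    sim = None
    if q.ifp_reference is not None:
        if rec.ifp is None:
            return False, None
        sim = ifp_similarity(rec.ifp, q.ifp_reference)
        if q.ifp_min_similarity is not None and sim < q.ifp_min_similarity:
            return False, None
    if (q.ligand_min_similarity is not None or q.ligand_max_similarity is not None):
        if q.ligand_reference is None:
            raise QueryError("ligand similarity clause needs ligand_reference")
        if rec.ligand_smiles is None:
            return False, None
        lsim = ligand_similarity(rec.ligand_smiles, q.ligand_reference,
                                 q.ligand_fp_kind)
        if q.ligand_min_similarity is not None and lsim < q.ligand_min_similarity:
            return False, None
        if q.ligand_max_similarity is not None and lsim > q.ligand_max_similarity:
            return False, None
    if q.substructure is not None:
        if rec.ligand_smiles is None:
            return False, None
        patt = Chem.MolFromSmarts(q.substructure)
        if patt is None:
            raise QueryError(f"substructure clause: bad pattern {q.substructure!r}")
        if not _mol_from_smiles(rec.ligand_smiles).HasSubstructMatch(patt):
            return False, None
    if q.exact_ligand is not None:
        if rec.ligand_smiles is None:
            return False, None
        if (canonical_tautomer_smiles(rec.ligand_smiles)
                != canonical_tautomer_smiles(q.exact_ligand)):
            return False, None
    ranges = dict(property_preset(q.property_preset)) if q.property_preset else {}
    ranges.update(q.property_ranges)
    if ranges:
        if not rec.ligand_properties:
            return False, None
        if not _check_ranges(rec.ligand_properties, ranges, rec.entry_id):
            return False, None
    if q.min_quality is not None and rec.quality_score < q.min_quality:
        return False, None
    if q.max_resolution is not None:
        if rec.resolution is None or rec.resolution > q.max_resolution:
            return False, None
    return True, sim


def evaluate_query(records: list[AnnotationRecord], q: Query,
                   ) -> list[AnnotationRecord]:
    """Records satisfying every clause of ``q``; deterministic ordering
    (descending fingerprint similarity when requested, then entry id)."""
    hits: list[tuple[AnnotationRecord, float | None]] = []
    for rec in records:
        ok, sim = _matches(rec, q)
        if ok:
            hits.append((rec, sim))
    if q.ifp_reference is not None:
        hits.sort(key=lambda t: (-(t[1] if t[1] is not None else -1.0),
                                 t[0].entry_id))
    else:
        hits.sort(key=lambda t: t[0].entry_id)
    return [rec for rec, _ in hits]


# ---------------------------------------------------------------------------
# Export

_EXPORT_COLUMNS = ("entry_id", "kinase", "family", "group", "species", "dfg",
                   "alpha_c", "quality_score", "rmsd_anchor", "rmsd_pocket",
                   "resolution", "pocket_sequence", "ligand_smiles",
                   "n_gaps", "subpockets", "water_labels", "ifp_hex")


def export_results(records: list[AnnotationRecord],
                   path: str | Path | None = None) -> str:
    """Export results as RFC-4180 CSV (UTF-8, stable column order);
    returns the CSV text and optionally writes it."""
    buf = io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")
    writer.writerow(_EXPORT_COLUMNS)
    for rec in records:
        writer.writerow([
            rec.entry_id, rec.kinase, rec.family, rec.group, rec.species,
            rec.dfg, rec.alpha_c, rec.quality_score, rec.rmsd_anchor,
            rec.rmsd_pocket, "" if rec.resolution is None else rec.resolution,
            rec.pocket_sequence, rec.ligand_smiles or "",
            len(rec.gap_slots),
            ";".join(sorted(k for k, v in rec.subpockets.items() if v)),
            ";".join(rec.water_labels),
            rec.ifp.to_hex() if rec.ifp is not None else "",
        ])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
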