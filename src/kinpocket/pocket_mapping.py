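"""Mapping kinase sequences onto the 85-residue binding-site numbering.

The binding site of the kinase catalytic domain is described by a fixed
set of 85 pocket positions, each carrying a region label (G-rich loop,
hinge, xDFG, ...).  A structure is mapped by aligning its chain sequence
to a bundled master profile; the master columns that constitute the
pocket are listed in a versioned region table.  Every structure yields
exactly 85 slots — unmapped positions become explicit gaps — which is
what makes fingerprints and conformational descriptors comparable across
the whole collection.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices

from .config import AlignmentConfig, DEFAULT_CONFIG
from .errors import InputError, NotKinaseDomainError, PocketUnresolvedError
from .model import Monomer, Residue
from .residues import AA3, expected_heavy_atoms

N_SLOTS = 85
GAP = "-"

# Pocket positions with a fixed role referenced throughout the package.
GATEKEEPER = 45
ALPHA_C_GLU = 24
XDFG_X, XDFG_D, XDFG_F, XDFG_G = 80, 81, 82, 83

# Regions whose residues anchor the structural superposition: catalytic
# loop, DFG motif and hinge.
ANCHOR_REGIONS = ("c.l", "xDFG", "hinge")


@dataclass(frozen=True)
class RegionTable:
    """Slot index -> region name and master-profile column (both 1-based)."""

    region: tuple[str, ...]          # region[i-1] for slot i
    master_column: tuple[int, ...]

    def region_of(self, index: int) -> str:
        _check_index(index)
        return self.region[index - 1]

    def column_of(self, index: int) -> int:
        _check_index(index)
        return self.master_column[index - 1]

    def slots_in_region(self, name: str) -> tuple[int, ...]:
        return tuple(i + 1 for i, r in enumerate(self.region) if r == name)

    @property
    def anchor_slots(self) -> tuple[int, ...]:
        out: list[int] = []
        for name in ANCHOR_REGIONS:
            out.extend(self.slots_in_region(name))
        return tuple(sorted(out))


def _check_index(index: int) -> None:
    if not 1 <= int(index) <= N_SLOTS:
        raise InputError(f"pocket index must be in 1..{N_SLOTS}, got {index}")


def _data_text(name: str) -> str:
    return resources.files("kinpocket.data").joinpath(name).read_text()


@lru_cache(maxsize=1)
def load_region_table() -> RegionTable:
    rows = list(csv.DictReader(io.StringIO(_data_text("region_table.csv"))))
    if len(rows) != N_SLOTS:
        raise InputError(f"region table must have {N_SLOTS} rows")
    rows.sort(key=lambda r: int(r["index"]))
    return RegionTable(
        region=tuple(r["region"] for r in rows),
        master_column=tuple(int(r["master_column"]) for r in rows),
    )


@lru_cache(maxsize=1)
def load_master_profile() -> list[tuple[str, str]]:
    """Bundled master alignment as (name, sequence) pairs; first entry is
    the consensus the structures are aligned against."""
    entries: list[tuple[str, str]] = []
    name, seq = None, []
    for line in _data_text("master_profile.fasta").splitlines():
        if line.startswith(">"):
            if name is not None:
                entries.append((name, "".join(seq)))
            name, seq = line[1:].split()[0], []
        elif line.strip():
            seq.append(line.strip())
    if name is not None:
        entries.append((name, "".join(seq)))
    return entries


def master_consensus() -> str:
    return load_master_profile()[0][1]


def master_pocket_sequence(table: RegionTable | None = None) -> str:
    """The 85 pocket residues of the master consensus."""
    table = table or load_region_table()
    cons = master_consensus()
    return "".join(cons[c - 1] for c in table.master_column)


def klifs_label(aa: str, index: int, table: RegionTable | None = None) -> str:
    """Render the binding-site label ``<aa>.<region>.<index>``,
    e.g. ``D.xDFG.81`` for the aspartate of the xDFG motif."""
    _check_index(index)
    table = table or load_region_table()
    return f"{aa}.{table.region_of(index)}.{index}"


# ---------------------------------------------------------------------------
# Alignment

@dataclass
class MasterAlignment:
    """Pairwise alignment of a query sequence against the master consensus.

    ``column_map[c]`` gives the 0-based query index aligned to master
    column ``c`` (1-based), or None when that column is deleted.
    """

    score: float
    column_map: dict[int, int | None]
    query: str
    aligned_pairs: tuple[tuple[int, int], ...] = ()

    def n_aligned(self) -> int:
        return sum(1 for v in self.column_map.values() if v is not None)


def _aligner(cfg: AlignmentConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(cfg.matrix)
    aligner.open_gap_score = -cfg.gap_open
    aligner.extend_gap_score = -cfg.gap_extend
    # glocal: unaligned termini on either side are free so that longer
    # constructs / shorter fragments still map onto the domain columns
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:      # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def align_to_master(sequence: str, cfg: AlignmentConfig | None = None,
                    master: str | None = None) -> MasterAlignment:
    """Align a chain sequence to the master consensus (BLOSUM62, gap open
    11 / extend 1, deterministic first-optimal traceback)."""
    cfg = cfg or DEFAULT_CONFIG.alignment
    sequence = sequence.upper()
    if len(sequence) < cfg.min_sequence_length:
        raise InputError(
            f"sequence too short ({len(sequence)} < {cfg.min_sequence_length})")
    master = master or master_consensus()
    clean = "".join(c if c in AA3 or c == "X" else "X" for c in sequence)
    aln = _aligner(cfg).align(master, clean)
    best = aln[0]
    if best.score < cfg.min_score:
        raise NotKinaseDomainError(
            f"alignment score {best.score:.1f} below floor {cfg.min_score}")
    column_map: dict[int, int | None] = {c: None for c in range(1, len(master) + 1)}
    pairs: list[tuple[int, int]] = []
    for (ts, te), (qs, qe) in zip(*best.aligned):
        for k in range(te - ts):
            column_map[ts + k + 1] = qs + k
            pairs.append((ts + k + 1, qs + k))
    return MasterAlignment(score=float(best.score), column_map=column_map,
                           query=sequence, aligned_pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# Pocket extraction

@dataclass
class PocketSlot:
    index: int
    region: str
    aa: str                    # one-letter code, '-' when gapped
    seqid: int | None          # author residue number in the structure
    residue: Residue | None    # live reference into the monomer
    missing_atoms: tuple[str, ...] = ()

    @property
    def is_gap(self) -> bool:
        return self.residue is None

    @property
    def label(self) -> str:
        return f"{self.aa}.{self.region}.{self.index}"


@dataclass
class PocketAlignment:
    """The 85-slot pocket of one monomer (always exactly 85 entries)."""

    kinase_id: str
    slots: list[PocketSlot]
    alignment_score: float = 0.0
    mutations: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.slots) != N_SLOTS:
            raise InputError(f"pocket must have exactly {N_SLOTS} slots")

    def slot(self, index: int) -> PocketSlot:
        _check_index(index)
        return self.slots[index - 1]

    @property
    def n_gaps(self) -> int:
        return sum(1 for s in self.slots if s.is_gap)

    @property
    def n_missing_atoms(self) -> int:
        return sum(len(s.missing_atoms) for s in self.slots)

    def pocket_sequence(self) -> str:
        return "".join(s.aa for s in self.slots)

    def to_fasta(self, name: str | None = None) -> str:
        return f">{name or self.kinase_id}\n{self.pocket_sequence()}\n"

    def to_rows(self) -> list[dict]:
        return [{
            "slot": s.index, "region": s.region, "label": s.label,
            "resnum": "" if s.seqid is None else s.seqid, "aa": s.aa,
            "gap": int(s.is_gap), "missing_atoms": ";".join(s.missing_atoms),
        } for s in self.slots]


def extract_pocket(alignment: MasterAlignment, monomer: Monomer,
                   table: RegionTable | None = None,
                   max_gaps: int = N_SLOTS // 2) -> PocketAlignment:
    """Project the master alignment onto the structure: one slot per pocket
    position, explicit gaps for unmapped/missing residues, and per-slot
    unresolved heavy atoms."""
    table = table or load_region_table()
    slots: list[PocketSlot] = []
    for index in range(1, N_SLOTS + 1):
        col = table.column_of(index)
        qidx = alignment.column_map.get(col)
        residue = monomer.residues[qidx] if qidx is not None and qidx < len(monomer.residues) else None
        if residue is None:
            slots.append(PocketSlot(index, table.region_of(index), GAP, None, None))
            continue
        expected = expected_heavy_atoms(residue.name)
        missing = tuple(a for a in expected if not residue.has_atom(a))
        slots.append(PocketSlot(index, table.region_of(index),
                                residue.one_letter, residue.seqid, residue,
                                missing_atoms=missing))
    pocket = PocketAlignment(kinase_id=monomer.source_id, slots=slots,
                             alignment_score=alignment.score)
    if pocket.n_gaps > max_gaps:
        raise PocketUnresolvedError(
            f"{pocket.n_gaps} of {N_SLOTS} pocket slots unresolved")
    return pocket


def detect_mutations(pocket: PocketAlignment,
                     reference_sequence: str) -> list[tuple[int, str, str]]:
    """Compare the observed pocket residues to an 85-character reference
    pocket sequence; gapped slots are excluded (nothing to compare)."""
    if len(reference_sequence) != N_SLOTS:
        raise InputError("reference must cover all 85 pocket positions")
    out: list[tuple[int, str, str]] = []
    for slot, ref in zip(pocket.slots, reference_sequence.upper()):
        if slot.is_gap:
            continue
        if slot.aa != ref:
            out.append((slot.index, ref, slot.aa))
    return out


def map_pocket(monomer: Monomer, cfg: AlignmentConfig | None = None,
               table: RegionTable | None = None) -> PocketAlignment:
    """Convenience: align the monomer sequence and extract its pocket,
    recording mutations against the master pocket sequence."""
    table = table or load_region_table()
    alignment = align_to_master(monomer.sequence(), cfg)
    pocket = extract_pocket(alignment, monomer, table)
    pocket.mutations = detect_mutations(pocket, master_pocket_sequence(table))
    return pocket
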