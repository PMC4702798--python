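"""End-to-end annotation: monomer -> AnnotationRecord.

The processing order mirrors the database build: map the pocket by
sequence alignment, superpose onto the master frame, classify entities,
compute the interaction fingerprint, conformations, subpocket flags,
water clusters and the quality score.
"""

from __future__ import annotations

from rdkit import Chem

from .config import Config, DEFAULT_CONFIG
from .conformation import annotate_conformation
from .fingerprint import compute_ifp
from .model import Monomer
from .pocket_mapping import (MasterAlignment, PocketAlignment, align_to_master,
                             detect_mutations, extract_pocket,
                             load_region_table, master_pocket_sequence)
from .pockets_waters import (SubpocketModel, WaterClusterSet,
                             assign_subpockets, assign_water_clusters,
                             default_subpocket_model, default_water_clusters)
from .search_engine import AnnotationRecord, ligand_descriptors
from .structure_prep import classify_entities
from .superposition import SuperpositionResult, quality_for, superpose


def remap_pocket(pocket: PocketAlignment, monomer: Monomer) -> PocketAlignment:
    """Re-point pocket slots at the residues of a (transformed) copy of
    the same monomer, matching by author residue number."""
    by_seqid = {r.seqid: r for r in monomer.residues}
    slots = []
    for s in pocket.slots:
        res = by_seqid.get(s.seqid) if s.seqid is not None else None
        slots.append(type(s)(s.index, s.region, s.aa if res else "-",
                             s.seqid if res else None, res, s.missing_atoms))
    return PocketAlignment(kinase_id=pocket.kinase_id, slots=slots,
                           alignment_score=pocket.alignment_score,
                           mutations=list(pocket.mutations))


def to_master_frame(monomer: Monomer,
                    cfg: Config | None = None,
                    ) -> tuple[Monomer, PocketAlignment, SuperpositionResult]:
    """Map the pocket, superpose on the master frame and return the
    transformed monomer with its (re-pointed) pocket."""
    cfg = cfg or DEFAULT_CONFIG
    alignment = align_to_master(monomer.sequence(), cfg.alignment)
    pocket = extract_pocket(alignment, monomer)
    pocket.mutations = detect_mutations(pocket, master_pocket_sequence())
    sup = superpose(pocket)
    transformed = sup.transform_monomer(monomer)
    return transformed, remap_pocket(pocket, transformed), sup


def annotate_monomer(monomer: Monomer,
                     dictionary=None,
                     subpocket_model: SubpocketModel | None = None,
                     water_clusters: WaterClusterSet | None = None,
                     cfg: Config | None = None,
                     resolution: float | None = None,
                     **identifiers) -> AnnotationRecord:
    """Produce the full annotation record for one monomer.

    ``identifiers`` may carry kinase/family/group/species names.  The
    subpocket model defaults to the bundled synthetic-corpus model and
    the water clusters to the versioned centroid file.
    """
    cfg = cfg or DEFAULT_CONFIG
    transformed, pocket, sup = to_master_frame(monomer, cfg)
    entities = classify_entities(transformed, pocket, dictionary, cfg.entities)
    ligand = entities.orthosteric_ligand
    ifp = compute_ifp(pocket, ligand, cfg.interactions)
    conf = annotate_conformation(pocket, cfg.conformation)
    subpockets = {}
    if ligand is not None:
        model = subpocket_model or default_subpocket_model()
        subpockets = assign_subpockets(ligand.coords(), model)
    waters = assign_water_clusters(
        entities.water_coords(), water_clusters or default_water_clusters(),
        pocket, ligand)
    quality = quality_for(pocket, sup, cfg.quality)
    smiles = None
    props: dict = {}
    if ligand is not None:
        smiles = Chem.MolToSmiles(Chem.RemoveHs(ligand.mol))
        props = ligand_descriptors(ligand.mol)
    return AnnotationRecord(
        entry_id=f"{monomer.source_id}_{monomer.model_index}{monomer.chain_id}",
        kinase=identifiers.get("kinase", ""),
        family=identifiers.get("family", ""),
        group=identifiers.get("group", ""),
        species=identifiers.get("species", ""),
        pocket_sequence=pocket.pocket_sequence(),
        gap_slots=tuple(s.index for s in pocket.slots if s.is_gap),
        mutations=tuple(tuple(m) for m in pocket.mutations),
        ifp=ifp, dfg=conf.dfg, alpha_c=conf.alpha_c, gloop=conf.gloop,
        conformation_descriptors={
            "asa_d81": conf.asa_d81, "yd": conf.yd, "yf": conf.yf,
            "d_f82_e24": conf.d_f82_e24},
        subpockets=subpockets,
        water_labels=tuple(w.label for w in waters),
        water_hbonds=tuple((w.label, w.hbond_ligand, w.hbond_protein)
                           for w in waters),
        quality_score=quality.score,
        rmsd_anchor=sup.rmsd_anchor, rmsd_pocket=sup.rmsd_pocket,
        resolution=resolution, ligand_smiles=smiles,
        ligand_properties=props)
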