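"""Entry splitting, alt-loc policy, ligand topology curation and entity
classification."""

import numpy as np
import pytest
import gemmi

from kinpocket.errors import EmptyEntryError, FormatError, InputError
from kinpocket.fixtures import (DesignedContact, FixtureSpec, generate_complex,
                                monomer_to_gemmi, write_complex)
from kinpocket.ligands import curate_ligand_topology, protonate_ph74, record_from_mol
from kinpocket.model import Atom, HeteroGroup
from kinpocket.pocket_mapping import map_pocket
from kinpocket.scaffold import pocket_of_domain
from kinpocket.structure_prep import (classify_entities, entity_manifest_csv,
                                      filter_homolog_hits, split_entry)


class TestHomologFilter:
    @pytest.mark.parametrize("identity,evalue,accepted", [
        (70.0, 0.001, True),      # both thresholds inclusive
        (69.9, 1e-50, False),     # identity below threshold
        (95.0, 0.01, False),      # e-value above threshold
        (100.0, 0.0, True),
    ])
    def test_thresholds(self, identity, evalue, accepted):
        got = filter_homolog_hits([(identity, evalue)])
        assert (got == [0]) == accepted

    def test_indices_preserved(self):
        hits = [(90.0, 1e-5), (50.0, 1e-5), (75.0, 1e-4)]
        assert filter_homolog_hits(hits) == [0, 2]

    def test_negative_evalue_rejected(self):
        with pytest.raises(InputError):
            filter_homolog_hits([(90.0, -1e-3)])

    def test_identity_range_checked(self):
        with pytest.raises(InputError):
            filter_homolog_hits([(120.0, 1e-5)])


def _write_two_chain_entry(tmp_path, n_models=1):
    fx = generate_complex(FixtureSpec(source_id="split"))
    st = monomer_to_gemmi(fx.monomer)
    model = st[0]
    chain_b = gemmi.Chain("B")
    for res in model["A"]:
        chain_b.add_residue(res)
    model.add_chain(chain_b)
    for extra in range(2, n_models + 1):
        st.add_model(st[0])
    path = tmp_path / "entry.pdb"
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def test_split_one_model_two_chains(tmp_path):
    path = _write_two_chain_entry(tmp_path)
    monomers = split_entry(path)
    assert len(monomers) == 2
    assert {m.chain_id for m in monomers} == {"A", "B"}
    assert all(m.model_index == 1 for m in monomers)


def test_split_two_models_one_chain(tmp_path):
    fx = generate_complex(FixtureSpec(source_id="twomodel"))
    st = monomer_to_gemmi(fx.monomer)
    second = st[0].clone()
    second.num = 2
    st.add_model(second)
    path = tmp_path / "two_models.pdb"
    st.write_pdb(str(path))
    monomers = split_entry(path)
    assert len(monomers) == 2
    assert sorted(m.model_index for m in monomers) == [1, 2]


def test_split_attaches_hetero_groups(tmp_path):
    fx = generate_complex(FixtureSpec(
        source_id="lig", contacts=(DesignedContact(47, "hbond_donor"),)))
    paths = write_complex(fx, tmp_path)
    (monomer,) = split_entry(paths["pdb"])
    assert len(monomer.hetero_groups) == 1
    assert monomer.hetero_groups[0].comp_id == "LIG"


def test_split_round_trips_coordinates(tmp_path):
    """split -> write -> split preserves atom counts and coordinates to
    3 decimals (PDB precision)."""
    fx = generate_complex(FixtureSpec(source_id="rt", waters=("I4",)))
    p1 = tmp_path / "a.pdb"
    monomer_to_gemmi(fx.monomer).write_pdb(str(p1))
    (m1,) = split_entry(p1)
    p2 = tmp_path / "b.pdb"
    monomer_to_gemmi(m1).write_pdb(str(p2))
    (m2,) = split_entry(p2)
    c1, c2 = m1.protein_coords(), m2.protein_coords()
    assert c1.shape == c2.shape
    assert np.abs(c1 - c2).max() < 1.5e-3


def test_unparseable_file_raises(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text("this is not a structure\n")
    with pytest.raises((FormatError, EmptyEntryError)):
        split_entry(bad)


def test_altloc_highest_occupancy_kept(tmp_path):
    fx = generate_complex(FixtureSpec(source_id="alt"))
    st = monomer_to_gemmi(fx.monomer)
    res = st[0]["A"][0]
    ca = [a for a in res if a.name == "CA"][0]
    ca.altloc = "A"
    ca.occ = 0.4
    alt = gemmi.Atom()
    alt.name = "CA"
    alt.element = ca.element
    alt.altloc = "B"
    alt.occ = 0.6
    alt.pos = gemmi.Position(ca.pos.x + 5.0, ca.pos.y, ca.pos.z)
    res.add_atom(alt)
    path = tmp_path / "alt.pdb"
    st.write_pdb(str(path))
    (m,) = split_entry(path)
    first = m.residues[0]
    cas = [a for a in first.atoms if a.name == "CA"]
    assert len(cas) == 1
    assert cas[0].altloc == "B"          # the 0.6-occupancy conformer


# ---------------------------------------------------------------------------
# Ligand curation

def _acetate_group(protonated=True):
    atoms = [Atom("C1", "C", (0.0, 0.0, 0.0)),
             Atom("C2", "C", (1.52, 0.0, 0.0)),
             Atom("O1", "O", (2.15, 1.06, 0.0)),
             Atom("O2", "O", (2.15, -1.06, 0.0))]
    return HeteroGroup("ACY", 1, "A", atoms)


def _acetate_dictionary():
    doc = gemmi.cif.read_string("""
data_ACY
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
ACY C1 C 0
ACY C2 C 0
ACY O1 O 0
ACY O2 O -1
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
ACY C1 C2 SING
ACY C2 O1 DOUB
ACY C2 O2 SING
""")
    return doc


def test_carboxylate_curated_from_dictionary():
    rec = curate_ligand_topology(_acetate_group(), _acetate_dictionary())
    assert rec.from_dictionary
    charges = {rec.atom_names[a.GetIdx()]: a.GetFormalCharge()
               for a in rec.mol.GetAtoms()}
    assert charges["O2"] == -1
    orders = sorted(str(b.GetBondType()) for b in rec.mol.GetBonds())
    assert orders.count("DOUBLE") == 1


def test_benzene_aromatic_perception_from_geometry():
    atoms = [Atom(f"C{k+1}", "C",
                  (1.39 * np.cos(np.radians(60 * k)),
                   1.39 * np.sin(np.radians(60 * k)), 0.0)) for k in range(6)]
    rec = curate_ligand_topology(HeteroGroup("BNZ", 1, "A", atoms), None)
    assert not rec.from_dictionary
    assert sum(1 for b in rec.mol.GetBonds() if b.GetIsAromatic()) == 6


def test_water_rejected_as_ligand():
    group = HeteroGroup("HOH", 1, "A", [Atom("O", "O", (0.0, 0.0, 0.0))])
    with pytest.raises(InputError):
        curate_ligand_topology(group, None)


def test_dictionary_name_mismatch_falls_back(recwarn):
    group = _acetate_group()
    for a in group.atoms:
        a.name = a.name.replace("C", "X").replace("O", "Q")
    doc = _acetate_dictionary()
    rec = curate_ligand_topology(group, doc)
    assert not rec.from_dictionary
    assert any("mismatch" in str(w.message) for w in recwarn.list)


def test_protonation_rules_and_idempotence():
    from rdkit import Chem
    mol = Chem.AddHs(Chem.MolFromSmiles("NCCCC(=O)O"))
    mol = Chem.RemoveHs(mol)
    changed = protonate_ph74(mol)
    assert changed
    charges = sorted(a.GetFormalCharge() for a in mol.GetAtoms()
                     if a.GetFormalCharge() != 0)
    assert charges == [-1, 1]
    assert protonate_ph74(mol) is False      # second pass is a no-op


def test_amide_not_protonated():
    from rdkit import Chem
    mol = Chem.MolFromSmiles("CC(=O)NC")
    assert protonate_ph74(mol) is False


# ---------------------------------------------------------------------------
# Entity classification

@pytest.fixture(scope="module")
def entity_fixture():
    fx = generate_complex(FixtureSpec(
        source_id="entities",
        contacts=(DesignedContact(47, "hbond_donor"),),
        waters=("I4", "I5"), extras=("ion", "cofactor", "allosteric")))
    pk = pocket_of_domain(fx.monomer)
    return fx, classify_entities(fx.monomer, pk)


def test_entity_partition_complete(entity_fixture):
    fx, entities = entity_fixture
    assert entities.n_groups == len(fx.monomer.hetero_groups)


def test_entity_categories(entity_fixture):
    fx, entities = entity_fixture
    assert [g.comp_id for g in entities.ions] == ["MG"]
    assert [g.comp_id for g in entities.cofactors] == ["ATP"]
    assert len(entities.waters) == 2
    assert len(entities.orthosteric) == 1
    assert entities.orthosteric[0][0].comp_id == "LIG"
    assert [g.comp_id for g, _ in entities.allosteric] == ["AL1"]


def test_remote_copy_is_allosteric(entity_fixture):
    _, entities = entity_fixture
    assert entities.orthosteric_ligand is not None
    assert entities.orthosteric_ligand.component_id == "LIG"


def test_entity_manifest_csv(entity_fixture):
    _, entities = entity_fixture
    text = entity_manifest_csv(entities)
    lines = text.strip().splitlines()
    assert lines[0].startswith("category,component")
    assert len(lines) == 1 + entities.n_groups
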