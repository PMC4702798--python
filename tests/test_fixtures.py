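"""Synthetic-complex generator: determinism, manifests, corpora, and the
self-consistency suite (every manifest claim re-verified by running the
full pipeline on the written files)."""

import json

import numpy as np
import pytest
import gemmi

from kinpocket.annotate import annotate_monomer
from kinpocket.errors import FixtureSpecError
from kinpocket.fingerprint import compute_ifp
from kinpocket.fixtures import (DesignedContact, FixtureSpec, generate_complex,
                                generate_corpus, generate_subpocket_corpus,
                                write_complex)
from kinpocket.scaffold import pocket_of_domain
from kinpocket.structure_prep import split_entry


def test_same_spec_same_seed_is_byte_identical(tmp_path):
    spec = FixtureSpec(source_id="det", seed=5, rigid_jumble=True,
                       noise_sigma=0.2,
                       contacts=(DesignedContact(47, "hbond_donor"),),
                       waters=("I4",))
    p1 = write_complex(generate_complex(spec), tmp_path / "a")
    p2 = write_complex(generate_complex(spec), tmp_path / "b")
    for key in p1:
        assert p1[key].read_bytes() == p2[key].read_bytes(), key


def test_single_hinge_hbond_manifest_has_one_bit():
    fx = generate_complex(FixtureSpec(
        source_id="one", contacts=(DesignedContact(47, "hbond_donor"),)))
    assert fx.manifest["designed_bits"] == [[47, "hbond_donor"]]
    assert fx.manifest["incidental_bits"] == []
    assert len(fx.manifest["expected_ifp_on_bits"]) == 1


def test_dfg_out_spec_flips_phe_vector():
    from kinpocket.conformation import dfg_vectors
    yf_in = dfg_vectors(pocket_of_domain(
        generate_complex(FixtureSpec(dfg="in")).monomer))[1]
    yf_out = dfg_vectors(pocket_of_domain(
        generate_complex(FixtureSpec(dfg="out")).monomer))[1]
    assert np.sign(yf_in) == -np.sign(yf_out)


def test_contradictory_contacts_rejected():
    with pytest.raises(FixtureSpecError):
        generate_complex(FixtureSpec(contacts=(
            DesignedContact(47, "hbond_donor"),
            DesignedContact(47, "hbond_donor"))))


def test_unknown_dfg_class_rejected():
    with pytest.raises(FixtureSpecError):
        generate_complex(FixtureSpec(dfg="sideways"))


def test_corpus_stratification():
    samples = generate_corpus(100, seed=3, noise_sigma=0.0, jumble=False)
    counts = {}
    for s in samples:
        counts[s.dfg_label] = counts.get(s.dfg_label, 0) + 1
    assert sorted(counts.values()) == [33, 33, 34]


def test_corpus_reproducible_from_seed():
    a = generate_corpus(12, seed=9)
    b = generate_corpus(12, seed=9)
    for sa, sb in zip(a, b):
        assert sa.dfg_label == sb.dfg_label
        assert np.allclose(sa.monomer.protein_coords(),
                           sb.monomer.protein_coords())


def test_subpocket_corpus_labels_are_geometric():
    from kinpocket.fixtures import subpocket_labels_for
    for coords, labels in generate_subpocket_corpus(20, seed=2):
        assert labels == subpocket_labels_for(coords)


def test_ligand_mol2_readable_by_rdkit(tmp_path):
    from rdkit import Chem
    fx = generate_complex(FixtureSpec(
        source_id="m2", contacts=(DesignedContact(47, "hbond_donor"),)))
    paths = write_complex(fx, tmp_path)
    mol = Chem.MolFromMol2File(str(paths["ligand_mol2"]), sanitize=False)
    assert mol is not None
    assert mol.GetNumAtoms() == fx.ligand.mol.GetNumAtoms()
    assert mol.GetNumBonds() == fx.ligand.mol.GetNumBonds()


@pytest.mark.parametrize("spec", [
    FixtureSpec(source_id="sc1",
                contacts=(DesignedContact(47, "hbond_donor"),)),
    FixtureSpec(source_id="sc2", seed=2, rigid_jumble=True,
                contacts=(DesignedContact(48, "hbond_acceptor"),
                          DesignedContact(36, "hydrophobic")),
                waters=("I4", "I5"), extras=("ion",)),
    FixtureSpec(source_id="sc3", seed=3, dfg="out",
                alpha_c_distance=10.5,
                pocket_substitutions={45: "M", 36: "K"},
                contacts=(DesignedContact(36, "ionic_positive"),),
                gap_slots=(60, 61)),
    FixtureSpec(source_id="sc4", seed=4, dfg="outlike",
                alpha_c_distance=8.2,
                pocket_substitutions={36: "F"},
                contacts=(DesignedContact(36, "aromatic_f2f"),),
                waters=("I7",), off_cluster_waters=((30.0, 30.0, 30.0),)),
])
def test_pipeline_reproduces_manifest_from_files(tmp_path, spec):
    """Self-consistency: write the fixture to disk, run the full pipeline
    (parse -> align -> superpose -> classify -> fingerprint -> waters) and
    compare every manifest claim."""
    fx = generate_complex(spec)
    paths = write_complex(fx, tmp_path)
    manifest = json.loads(paths["manifest"].read_text())
    (monomer,) = split_entry(paths["pdb"])
    ccd = gemmi.cif.read(str(paths["dictionary"])) if "dictionary" in paths else None
    rec = annotate_monomer(monomer, dictionary=ccd)

    assert rec.dfg == manifest["dfg"]
    assert rec.alpha_c == manifest["alpha_c"]
    assert sorted(rec.gap_slots) == manifest["gap_slots"]
    assert [list(m) for m in rec.mutations] == manifest["mutations"]
    assert rec.ifp.on_bits() == manifest["expected_ifp_on_bits"]
    assert sorted(rec.water_labels) == sorted(manifest["water_labels"])
    assert rec.ifp.apo == manifest["apo"]
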