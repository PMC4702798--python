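"""Query engine: worked-example query shapes, presets, export."""

import dataclasses

import numpy as np
import pytest

from kinpocket.annotate import annotate_monomer
from kinpocket.errors import QueryError
from kinpocket.fingerprint import InteractionPattern
from kinpocket.fixtures import DesignedContact, FixtureSpec, generate_complex
from kinpocket.search_engine import (AnnotationRecord, Query, evaluate_query,
                                     export_results, ligand_similarity,
                                     load_collection, property_preset,
                                     save_collection)

SORAFENIB = "CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1"
QUINAZOLINE = "c1ccc2ncncc2c1"


def _record(source_id, contacts, substitutions=None, waters=(), occupy=(),
            smiles=None, seed=0):
    fx = generate_complex(FixtureSpec(
        source_id=source_id, seed=seed, contacts=contacts,
        pocket_substitutions=substitutions or {}, waters=waters,
        occupy_subpockets=occupy))
    rec = annotate_monomer(fx.monomer, dictionary=fx.dictionary())
    if smiles is not None:
        rec = dataclasses.replace(rec, ligand_smiles=smiles)
    return rec


@pytest.fixture(scope="module")
def collection():
    """Engineered collection with known satisfiers for each query shape."""
    front_gate = (DesignedContact(47, "hbond_donor"),
                  DesignedContact(45, "hydrophobic"))
    fg_occupy = ("FP-I", "BP-I-A")
    return [
        _record("btk_hit1", front_gate, occupy=fg_occupy, smiles=SORAFENIB),
        _record("btk_hit2", front_gate, occupy=fg_occupy,
                waters=("I4", "I5"), smiles=SORAFENIB),
        _record("gk_met", front_gate, occupy=fg_occupy,
                substitutions={45: "M"}, smiles=SORAFENIB),
        _record("backfull", front_gate, occupy=fg_occupy + ("BP-II-in",),
                smiles=SORAFENIB),
        _record("apo", ()),
        # chemically-distinct ligand sharing the interaction pattern
        _record("sor_sim", front_gate, occupy=fg_occupy, smiles=QUINAZOLINE),
    ]


def test_empty_query_matches_all(collection):
    assert len(evaluate_query(collection, Query())) == len(collection)


def test_gatekeeper_front_gate_not_back_query(collection):
    """Selective-inhibitor query shape: threonine gatekeeper and a ligand
    in front cleft and gate area but not the back cleft."""
    q = Query(pocket_composition={45: "T"},
              subpockets_present=("front_cleft", "gate_area"),
              subpockets_absent=("back_cleft",))
    hits = evaluate_query(collection, q)
    assert [r.entry_id for r in hits] == ["btk_hit1_1A", "btk_hit2_1A",
                                         "sor_sim_1A"]


def test_water_and_composition_query(collection):
    """Conserved-water query shape: waters I4+I5 plus the key pocket
    residues (T gatekeeper, V in the b.l loop, A at xDFG.80)."""
    q = Query(waters_present=("I4", "I5"),
              pocket_composition={45: "T", 36: "V", 80: "A"})
    hits = evaluate_query(collection, q)
    assert [r.entry_id for r in hits] == ["btk_hit2_1A"]


def test_similar_ifp_dissimilar_ligand_query(collection):
    """Scaffold-hopping query shape: interaction-similar (>= 0.75) but
    chemically dissimilar (Morgan <= 0.25) to a reference complex."""
    ref = next(r for r in collection if r.entry_id == "btk_hit1_1A")
    sim_only = Query(ifp_reference=ref.ifp, ifp_min_similarity=0.75)
    combined = dataclasses.replace(
        sim_only, ligand_reference=ref.ligand_smiles,
        ligand_max_similarity=0.25)
    hits_sim = evaluate_query(collection, sim_only)
    hits_combined = evaluate_query(collection, combined)
    assert {r.entry_id for r in hits_combined} <= {r.entry_id for r in hits_sim}
    assert [r.entry_id for r in hits_combined] == ["sor_sim_1A"]
    assert ligand_similarity(SORAFENIB, QUINAZOLINE) <= 0.25


def test_interaction_pattern_clause(collection):
    q = Query(interaction_pattern=InteractionPattern(
        ((47, "hbond_donor", "present"),)))
    hits = evaluate_query(collection, q)
    assert "apo_1A" not in {r.entry_id for r in hits}
    assert "btk_hit1_1A" in {r.entry_id for r in hits}


def test_adding_clause_never_grows_results(collection):
    base = Query(subpockets_present=("front_cleft",))
    refined = dataclasses.replace(base, pocket_composition={45: "T"})
    assert {r.entry_id for r in evaluate_query(collection, refined)} <= \
        {r.entry_id for r in evaluate_query(collection, base)}


def test_similarity_ordering_descending(collection):
    ref = next(r for r in collection if r.entry_id == "btk_hit1_1A")
    hits = evaluate_query(collection, Query(ifp_reference=ref.ifp))
    from kinpocket.fingerprint import ifp_similarity
    sims = [ifp_similarity(r.ifp, ref.ifp) for r in hits]
    assert sims == sorted(sims, reverse=True)


def test_malformed_clause_names_itself(collection):
    with pytest.raises(QueryError, match="similarity clause"):
        evaluate_query(collection, Query(ligand_min_similarity=0.5))


class TestPresets:
    def test_rule_of_five_excludes_heavy(self):
        rec = AnnotationRecord(entry_id="x", ligand_smiles="C",
                               ligand_properties={"mw": 550.0, "logp": 2.0,
                                                  "hbd": 1, "hba": 3})
        assert evaluate_query([rec], Query(property_preset="rule-of-five")) == []

    def test_rule_of_three_includes_small(self):
        rec = AnnotationRecord(entry_id="x", ligand_smiles="C",
                               ligand_properties={"mw": 250.0, "logp": 2.0,
                                                  "hbd": 2, "hba": 3,
                                                  "rotatable": 2})
        assert len(evaluate_query([rec], Query(property_preset="rule-of-three"))) == 1

    def test_manual_override_takes_precedence(self):
        rec = AnnotationRecord(entry_id="x", ligand_smiles="C",
                               ligand_properties={"mw": 550.0, "logp": 2.0,
                                                  "hbd": 1, "hba": 3})
        q = Query(property_preset="rule-of-five",
                  property_ranges={"mw": (None, 600.0)})
        assert len(evaluate_query([rec], q)) == 1

    def test_unknown_preset(self):
        with pytest.raises(QueryError):
            property_preset("rule-of-nine")


class TestExport:
    def test_header_and_rows(self, collection):
        text = export_results(collection[:3])
        lines = text.strip().split("\n")
        assert len(lines) == 4
        assert lines[0].startswith("entry_id,")

    def test_comma_fields_quoted(self):
        rec = AnnotationRecord(entry_id="a,b")
        text = export_results([rec])
        assert '"a,b"' in text

    def test_round_trip_values(self, tmp_path, collection):
        import csv
        path = tmp_path / "out.csv"
        export_results(collection, path)
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == len(collection)
        for rec, row in zip(collection, rows):
            assert row["entry_id"] == rec.entry_id
            assert row["dfg"] == rec.dfg
            assert float(row["quality_score"]) == pytest.approx(rec.quality_score)


def test_collection_store_round_trip(tmp_path, collection):
    save_collection(collection, tmp_path / "store")
    loaded = load_collection(tmp_path / "store")
    assert len(loaded) == len(collection)
    by_id = {r.entry_id: r for r in loaded}
    for rec in collection:
        got = by_id[rec.entry_id]
        assert got.pocket_sequence == rec.pocket_sequence
        assert got.dfg == rec.dfg
        assert got.subpockets == rec.subpockets
        if rec.ifp is not None:
            assert got.ifp.on_bits() == rec.ifp.on_bits()
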