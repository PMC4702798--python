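"""Subpocket probe model and conserved water clusters."""

import numpy as np
import pytest

from kinpocket.config import SubpocketConfig
from kinpocket.errors import InputError
from kinpocket.fixtures import (DesignedContact, FixtureSpec, TRUE_WATER_SITES,
                                generate_complex, generate_subpocket_corpus,
                                generate_water_corpus)
from kinpocket.pockets_waters import (MAJOR_LABELS, SUBPOCKET_LABELS,
                                      WaterClusterSet, assign_subpockets,
                                      assign_water_clusters,
                                      default_water_clusters,
                                      derive_water_clusters, major_of,
                                      train_subpocket_model)
from kinpocket.scaffold import pocket_of_domain


@pytest.fixture(scope="module")
def corpus():
    return generate_subpocket_corpus(120, seed=1)


@pytest.fixture(scope="module")
def model(corpus):
    return train_subpocket_model(corpus[:96])


def test_every_trained_label_has_probes(model):
    for label in (*MAJOR_LABELS, *SUBPOCKET_LABELS):
        assert model.n_probes(label) >= 1


def test_disjoint_clouds_give_disjoint_probe_sets():
    a = np.random.default_rng(1).normal((0, 0, 0), 0.4, (30, 3))
    b = np.random.default_rng(2).normal((10, 0, 0), 0.4, (30, 3))
    training = [(a, {"A"}), (b, {"B"})] * 3
    m = train_subpocket_model(training)
    da = np.linalg.norm(m.probes["A"][:, None] - m.probes["B"][None], axis=-1)
    assert da.min() > 5.0


def test_identical_positives_and_negatives_give_empty_label(recwarn):
    cloud = np.random.default_rng(3).normal(0, 0.5, (20, 3))
    training = [(cloud, {"A"}), (cloud.copy(), set())] * 2
    m = train_subpocket_model(training)
    assert m.n_probes("A") == 0 or "A" not in m.probes


def test_grid_halving_multiplies_probe_count():
    rng = np.random.default_rng(4)
    training = [(rng.uniform(-2, 2, (200, 3)), {"A"}) for _ in range(4)]
    training += [(rng.normal((15, 0, 0), 1, (50, 3)), set()) for _ in range(2)]
    coarse = train_subpocket_model(
        training, SubpocketConfig(grid_spacing=1.0, top_k=10 ** 6))
    fine = train_subpocket_model(
        training, SubpocketConfig(grid_spacing=0.5, top_k=10 ** 6))
    ratio = fine.n_probes("A") / coarse.n_probes("A")
    assert 5.0 < ratio < 11.0     # ~x8 with boundary effects


def test_probe_contact_assignment(model):
    probe = model.probes["FP-I"][0]
    flags = assign_subpockets(probe[None, :], model)
    assert flags["FP-I"] and flags["front_cleft"]
    far = assign_subpockets(np.array([[50.0, 50.0, 50.0]]), model)
    assert not any(far.values())


def test_assignment_monotone_in_atom_set(model, corpus):
    coords, _ = corpus[100]
    base = assign_subpockets(coords, model)
    grown = assign_subpockets(
        np.vstack([coords, [[0.0, -4.5, 2.5]]]), model)
    for label, val in base.items():
        if val:
            assert grown[label]


def test_hierarchy_subpocket_implies_major(model, corpus):
    for coords, _ in corpus[:40]:
        flags = assign_subpockets(coords, model)
        for label, val in flags.items():
            if val and major_of(label):
                assert flags[major_of(label)]


def test_empty_model_rejected():
    from kinpocket.pockets_waters import SubpocketModel
    with pytest.raises(InputError):
        assign_subpockets(np.zeros((1, 3)),
                          SubpocketModel({}, 0.5, 1.0))


def test_training_deterministic(corpus):
    m1 = train_subpocket_model(corpus[:50])
    m2 = train_subpocket_model(corpus[:50])
    assert m1.labels() == m2.labels()
    for label in m1.labels():
        assert np.array_equal(m1.probes[label], m2.probes[label])


def test_model_save_load_round_trip(tmp_path, model):
    model.save(tmp_path)
    loaded = type(model).load(tmp_path)
    assert loaded.labels() == model.labels()
    for label in model.labels():
        assert np.allclose(loaded.probes[label], model.probes[label], atol=1e-3)
    assert loaded.contact_radius == model.contact_radius


# ---------------------------------------------------------------------------
# Water clusters

def test_derivation_recovers_13_sites():
    wcs = derive_water_clusters(generate_water_corpus(60, seed=5),
                                reference_labels=TRUE_WATER_SITES)
    assert len(wcs.centroids) == 13
    for label, centroid in wcs.centroids.items():
        true = np.array(TRUE_WATER_SITES[label])
        assert np.linalg.norm(np.array(centroid) - true) < 0.5


def test_derivation_reproducible():
    obs = generate_water_corpus(40, seed=7)
    a = derive_water_clusters(obs, reference_labels=TRUE_WATER_SITES)
    b = derive_water_clusters(obs, reference_labels=TRUE_WATER_SITES)
    assert a.centroids == b.centroids


def test_out_specific_labels_flag_dfg_out_sites():
    wcs = default_water_clusters()
    assert set(wcs.dfg_out_specific) == {"O1", "O2"}
    for label in wcs.dfg_out_specific:
        true = np.array(TRUE_WATER_SITES[label])
        assert np.linalg.norm(np.array(wcs.centroids[label]) - true) < 0.5


def test_water_at_centroid_assigned():
    wcs = default_water_clusters()
    w = np.array([wcs.centroids["I5"]])
    (a,) = assign_water_clusters(w, wcs)
    assert a.label == "I5"


def test_equidistant_water_takes_lowest_label():
    centroids = {f"I{i}": (float(i * 10), 0.0, 0.0) for i in range(1, 12)}
    centroids["O1"] = (0.0, 50.0, 0.0)
    centroids["O2"] = (0.0, 60.0, 0.0)
    centroids["I4"] = (0.0, 0.0, 0.0)
    centroids["I5"] = (2.0, 0.0, 0.0)
    wcs = WaterClusterSet(centroids=centroids, assignment_radius=1.5)
    (a,) = assign_water_clusters(np.array([[1.0, 0.0, 0.0]]), wcs)
    assert a.label == "I4"       # exactly between I4 and I5


def test_far_water_dropped():
    wcs = default_water_clusters()
    assert assign_water_clusters(np.array([[99.0, 99.0, 99.0]]), wcs) == []


def test_assignment_is_partition():
    wcs = default_water_clusters()
    rng = np.random.default_rng(9)
    waters = np.array([np.array(c) + rng.normal(0, 0.3, 3)
                       for c in wcs.centroids.values()])
    assigned = assign_water_clusters(waters, wcs)
    assert len(assigned) == len({a.position for a in assigned})
    for a in assigned:
        assert sum(a.label == b.label for b in assigned) == 1


def test_water_hbond_pattern_with_ligand_and_protein():
    fx = generate_complex(FixtureSpec(
        source_id="wat", contacts=(DesignedContact(47, "hbond_donor"),),
        waters=("I4",)))
    pk = pocket_of_domain(fx.monomer)
    waters = np.array([h.atoms[0].pos for h in fx.monomer.hetero_groups
                       if h.comp_id == "HOH"])
    assigned = assign_water_clusters(waters, default_water_clusters(), pk,
                                     fx.ligand)
    assert len(assigned) == 1
    assert assigned[0].label == "I4"
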