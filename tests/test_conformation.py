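"""ASA engine, DFG vectors/classifier, aC classes and G-loop descriptors."""

import numpy as np
import pytest

from kinpocket.conformation import (accessible_surface_area, alpha_c_distance,
                                    classify_alpha_c, classify_dfg,
                                    default_dfg_tree, dfg_descriptors,
                                    dfg_vectors, gloop_descriptors,
                                    shrake_rupley, train_dfg_tree)
from kinpocket.errors import UndefinedDescriptorError
from kinpocket.fixtures import FixtureSpec, generate_complex
from kinpocket.geometry import random_rotation
from kinpocket.scaffold import build_domain, pocket_of_domain
from kinpocket.superposition import superpose

# Golden master-frame descriptor values, frozen at model-build time.
MASTER_GLOOP = (49.7045, 13.5180, -78.5383)
MASTER_AC_DISTANCE = 6.4529


# ---------------------------------------------------------------------------
# Shrake-Rupley ASA

def test_isolated_atom_matches_sphere_area():
    asa = shrake_rupley(np.zeros((1, 3)), ["C"], probe_radius=1.4, n_points=960)
    assert asa[0] == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=1e-6)


def test_two_sphere_union_matches_analytic_caps():
    """Two overlapping equal spheres: exposed area per sphere follows the
    spherical-cap formula A = 4*pi*R^2 - 2*pi*R*h with h = R - d/2."""
    r = 1.70 + 1.4
    d = 2.0
    asa = shrake_rupley(np.array([[0, 0, 0], [d, 0, 0.0]]), ["C", "C"],
                        n_points=8000)
    h = r - d / 2
    expected = 4 * np.pi * r ** 2 - 2 * np.pi * r * h
    assert asa[0] == pytest.approx(expected, rel=0.01)
    assert asa[1] == pytest.approx(expected, rel=0.01)


def test_free_aspartate_matches_high_resolution_integration():
    """Sphere-union area of an isolated aspartate side-chain group via the
    default lattice vs a 100k-point numerical integration."""
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.1, 0], [2.2, -1.1, 0.0]])
    elements = ["C", "C", "O", "O"]
    coarse = shrake_rupley(coords, elements, n_points=960).sum()
    fine = shrake_rupley(coords, elements, n_points=100_000).sum()
    assert coarse == pytest.approx(fine, rel=0.02)


def test_asa_convergence_on_doubling():
    rng = np.random.default_rng(8)
    coords = rng.uniform(-3, 3, size=(15, 3))
    elements = ["C", "N", "O"] * 5
    a1 = shrake_rupley(coords, elements, n_points=960).sum()
    a2 = shrake_rupley(coords, elements, n_points=1920).sum()
    assert abs(a1 - a2) / a2 < 0.01


def test_buried_atom_has_near_zero_asa():
    # cage of atoms on a sphere of radius 3 around a central carbon
    rng = np.random.default_rng(0)
    n = 200
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    shell = 3.0 * np.stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1)
    coords = np.vstack([[0.0, 0.0, 0.0], shell])
    asa = shrake_rupley(coords, ["C"] * len(coords), n_points=960,
                        indices=np.array([0]))
    assert asa[0] < 1.0


def test_gap_residue_asa_undefined(master_pk):
    monomer = build_domain(delete_slots=(81,))
    pk = pocket_of_domain(monomer)
    with pytest.raises(UndefinedDescriptorError):
        accessible_surface_area(pk, 81)


# ---------------------------------------------------------------------------
# DFG vectors and classifier

def test_dfg_vectors_direct_subtraction(master_pk):
    yd, yf = dfg_vectors(master_pk)
    d81 = master_pk.slot(81).residue
    assert yd == pytest.approx((d81.coord("CG") - d81.coord("CA"))[1])


def test_dfg_vectors_frame_fixed_by_superposition():
    rng = np.random.default_rng(21)
    base = build_domain()
    yd0, yf0 = dfg_vectors(pocket_of_domain(base))
    moved = base.transformed(random_rotation(rng), rng.uniform(-15, 15, 3))
    sup = superpose(pocket_of_domain(moved))
    back = sup.transform_monomer(moved)
    yd1, yf1 = dfg_vectors(pocket_of_domain(back))
    assert yd1 == pytest.approx(yd0, abs=1e-6)
    assert yf1 == pytest.approx(yf0, abs=1e-6)


def test_dfg_out_flips_phe_vector_sign():
    _, yf_in = dfg_vectors(pocket_of_domain(build_domain(dfg="in")))
    _, yf_out = dfg_vectors(pocket_of_domain(build_domain(dfg="out")))
    assert yf_in < 0 < yf_out


def test_classifier_recovers_canonical_fixtures():
    tree = default_dfg_tree()
    for dfg in ("in", "out", "outlike"):
        pk = pocket_of_domain(build_domain(dfg=dfg))
        assert classify_dfg(dfg_descriptors(pk), tree) == f"DFG-{dfg}"


def test_classifier_unknown_on_missing_descriptors():
    assert classify_dfg(None) == "unknown"


def test_missing_cg_is_undefined():
    monomer = build_domain(truncate_atoms={82: ("N", "CA", "C", "O", "CB")})
    with pytest.raises(UndefinedDescriptorError):
        dfg_vectors(pocket_of_domain(monomer))


# ---------------------------------------------------------------------------
# aC-helix

def test_alpha_c_distance_master(master_pk):
    assert alpha_c_distance(master_pk) == pytest.approx(MASTER_AC_DISTANCE, abs=1e-3)


@pytest.mark.parametrize("d,expected", [
    (6.5, "aC-in"),
    (7.2, "aC-in"),          # boundary inclusive
    (8.0, "aC-outlike"),
    (9.3, "aC-outlike"),
    (12.0, "aC-out"),
])
def test_alpha_c_classes(d, expected):
    pk = pocket_of_domain(build_domain(alpha_c_distance=d))
    assert alpha_c_distance(pk) == pytest.approx(d, abs=1e-6)
    assert classify_alpha_c(pk) == expected


def test_alpha_c_monotone():
    order = {"aC-in": 0, "aC-outlike": 1, "aC-out": 2}
    prev = -1
    for d in np.linspace(5.5, 13.0, 16):
        cls = classify_alpha_c(pocket_of_domain(build_domain(alpha_c_distance=float(d))))
        assert order[cls] >= prev
        prev = order[cls]


def test_alpha_c_unknown_when_residue_missing():
    monomer = build_domain(delete_slots=(24,))
    assert classify_alpha_c(pocket_of_domain(monomer)) == "unknown"


# ---------------------------------------------------------------------------
# G-rich loop

def test_gloop_master_golden_triple(master_pk):
    angle, dist, rot = gloop_descriptors(master_pk)
    assert angle == pytest.approx(MASTER_GLOOP[0], abs=1e-3)
    assert dist == pytest.approx(MASTER_GLOOP[1], abs=1e-3)
    assert rot == pytest.approx(MASTER_GLOOP[2], abs=1e-3)


def test_gloop_invariant_under_translation():
    moved = build_domain().transformed(np.eye(3), np.array([5.0, -3.0, 12.0]))
    angle, dist, rot = gloop_descriptors(pocket_of_domain(moved))
    assert (angle, dist, rot) == pytest.approx(MASTER_GLOOP, abs=1e-3)


def test_gloop_lift_increases_distance():
    base = gloop_descriptors(pocket_of_domain(build_domain()))[1]
    lifted = gloop_descriptors(pocket_of_domain(build_domain(gloop_lift=3.0)))[1]
    assert lifted - base == pytest.approx(3.0, abs=0.05)


def test_gloop_undefined_when_region_gone():
    monomer = build_domain(delete_slots=(4, 5, 6, 7, 8, 9))
    with pytest.raises(UndefinedDescriptorError):
        gloop_descriptors(pocket_of_domain(monomer))


# ---------------------------------------------------------------------------
# Training harness

def test_training_harness_reaches_perfect_cv_on_clean_classes():
    rng = np.random.default_rng(4)
    rows, labels = [], []
    for cls, (yd, yf) in {"DFG-in": (2.5, -1.9), "DFG-out": (-2.4, 2.3),
                          "DFG-outlike": (0.3, -1.8)}.items():
        for _ in range(20):
            rows.append({"asa_d81": float(rng.uniform(20, 50)),
                         "yd": yd + rng.normal(0, 0.2),
                         "yf": yf + rng.normal(0, 0.2)})
            labels.append(cls)
    tree, acc = train_dfg_tree(rows, labels, n_folds=5, seed=0)
    assert acc == pytest.approx(1.0)
    assert tree.predict({"asa_d81": 30.0, "yd": 2.4, "yf": -1.8}) == "DFG-in"
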