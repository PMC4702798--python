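"""Interaction fingerprint: geometry rules, gap handling, similarity,
patterns."""

import numpy as np
import pytest

from kinpocket.errors import InputError
from kinpocket.fingerprint import (InteractionFingerprint, InteractionPattern,
                                   N_BITS, compute_ifp, ifp_similarity,
                                   match_pattern)
from kinpocket.fixtures import DesignedContact, FixtureSpec, generate_complex
from kinpocket.geometry import random_rotation
from kinpocket.scaffold import pocket_of_domain


def _fp(on):
    return InteractionFingerprint.from_on_bits(on)


class TestSimilarity:
    def test_identical_nonzero(self):
        a = _fp([1, 10, 100])
        assert ifp_similarity(a, a) == 1.0

    def test_disjoint(self):
        assert ifp_similarity(_fp([1, 2]), _fp([3, 4])) == 0.0

    def test_partial_overlap(self):
        assert ifp_similarity(_fp([1, 2, 3]), _fp([2, 3, 4])) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        assert ifp_similarity(_fp([]), _fp([])) == 1.0

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = _fp(list(rng.choice(N_BITS, size=10, replace=False)))
            b = _fp(list(rng.choice(N_BITS, size=10, replace=False)))
            s1, s2 = ifp_similarity(a, b), ifp_similarity(b, a)
            assert s1 == s2
            assert 0.0 <= s1 <= 1.0
            assert (s1 == 1.0) == (a.on_bits() == b.on_bits())


def test_fingerprint_length_enforced():
    with pytest.raises(InputError):
        InteractionFingerprint(bits=np.zeros(100, dtype=np.uint8))


def test_hex_round_trip():
    fp = _fp([0, 7, 100, 594])
    assert InteractionFingerprint.from_hex(fp.to_hex()).on_bits() == fp.on_bits()


def test_apo_structure_gives_flagged_zero_fingerprint(master_pk):
    fp = compute_ifp(master_pk, None)
    assert fp.apo
    assert len(fp) == N_BITS
    assert fp.count() == 0


def test_gap_inserts_seven_zeroes():
    fx = generate_complex(FixtureSpec(
        source_id="gaptest", contacts=(DesignedContact(47, "hbond_donor"),),
        gap_slots=(42,)))
    pk = pocket_of_domain(fx.monomer)
    fp = compute_ifp(pk, fx.ligand)
    assert len(fp) == N_BITS
    assert fp.block(42).sum() == 0
    # 1-based bit positions 288..294 correspond to block 42
    assert fp.bits[287:294].sum() == 0
    assert fp.get(47, "hbond_donor") == 1


def test_single_designed_hbond_gives_single_block():
    fx = generate_complex(FixtureSpec(
        source_id="single", contacts=(DesignedContact(47, "hbond_donor"),)))
    pk = pocket_of_domain(fx.monomer)
    fp = compute_ifp(pk, fx.ligand)
    assert fp.on_bits() == [(47 - 1) * 7 + 3]


def test_rigid_transform_invariance():
    """Fingerprints do not change when pocket and ligand move together."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D
    from kinpocket.ligands import record_from_mol

    fx = generate_complex(FixtureSpec(
        source_id="rigid",
        contacts=(DesignedContact(47, "hbond_donor"),
                  DesignedContact(36, "hydrophobic"))))
    pk = pocket_of_domain(fx.monomer)
    fp0 = compute_ifp(pk, fx.ligand)
    rng = np.random.default_rng(9)
    for _ in range(3):
        r, t = random_rotation(rng), rng.uniform(-30, 30, 3)
        moved = fx.monomer.transformed(r, t)
        mol = Chem.Mol(fx.ligand.mol)
        conf = mol.GetConformer()
        for i in range(mol.GetNumAtoms()):
            p = np.array(list(conf.GetAtomPosition(i)))
            conf.SetAtomPosition(i, Point3D(*(r @ p + t)))
        lig = record_from_mol("LIG", mol)
        fp1 = compute_ifp(pocket_of_domain(moved), lig)
        assert fp1.on_bits() == fp0.on_bits()


def test_distant_ligand_gives_empty_block(master_pk, toy_ligand_factory):
    rng = np.random.default_rng(1)
    lig = toy_ligand_factory(rng, far=True)
    fp = compute_ifp(master_pk, lig)
    assert fp.count() == 0


class TestPattern:
    def test_empty_pattern_matches(self):
        assert match_pattern(_fp([5]), InteractionPattern())

    def test_present_and_absent(self):
        fx = generate_complex(FixtureSpec(
            source_id="pat", contacts=(DesignedContact(47, "hbond_donor"),)))
        fp = compute_ifp(pocket_of_domain(fx.monomer), fx.ligand)
        assert match_pattern(fp, InteractionPattern(
            ((47, "hbond_donor", "present"),)))
        assert not match_pattern(fp, InteractionPattern(
            ((47, "hbond_donor", "absent"),)))
        assert match_pattern(fp, InteractionPattern(
            ((12, "ionic_positive", "absent"), (47, "hbond_donor", "any"))))

    def test_pattern_validation(self):
        with pytest.raises(InputError):
            InteractionPattern(((0, "hydrophobic", "present"),))
        with pytest.raises(InputError):
            InteractionPattern(((5, "nonsense", "present"),))
        with pytest.raises(InputError):
            InteractionPattern(((5, "hydrophobic", "maybe"),))


def test_detector_matches_brute_force_oracle(master_pk, toy_ligand_factory):
    """Vectorized detector vs the independent all-pairs checker,
    bit-for-bit, over random toy complexes."""
    from oracle_ifp import brute_force_ifp

    rng = np.random.default_rng(2024)
    for k in range(60):
        lig = toy_ligand_factory(rng, far=(k % 10 == 9))
        fast = compute_ifp(master_pk, lig)
        slow = brute_force_ifp(master_pk, lig)
        assert fast.bits.tolist() == slow, f"complex {k} disagrees"
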