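"""Shared fixtures: master frame objects and random toy ligands."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Geometry import Point3D

from kinpocket.geometry import random_rotation
from kinpocket.ligands import record_from_mol
from kinpocket.scaffold import master_frame, master_pocket


@pytest.fixture(scope="session")
def master():
    return master_frame()


@pytest.fixture(scope="session")
def master_pk():
    return master_pocket()


# ---------------------------------------------------------------------------
# Random toy ligands covering every interaction-relevant chemotype

def _template(smiles: str, coords: list[tuple[float, float, float]]) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    mol = Chem.RemoveHs(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*xyz))
    mol.AddConformer(conf)
    return mol


def _benzene() -> Chem.Mol:
    coords = [(1.39 * np.cos(np.radians(60 * k)),
               1.39 * np.sin(np.radians(60 * k)), 0.0) for k in range(6)]
    return _template("c1ccccc1", coords)


def _acetate() -> Chem.Mol:
    return _template("CC(=O)[O-]",
                     [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0),
                      (2.15, 1.05, 0.0), (2.15, -1.05, 0.0)])


def _methylamine() -> Chem.Mol:
    return _template("C[NH3+]", [(0.0, 0.0, 0.0), (1.47, 0.0, 0.0)])


def _acetamide() -> Chem.Mol:
    return _template("CC(=O)N",
                     [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0),
                      (2.15, 1.05, 0.0), (2.15, -1.15, 0.0)])


def _propane() -> Chem.Mol:
    return _template("CCC", [(0.0, 0.0, 0.0), (1.5, 0.3, 0.0), (2.6, -0.7, 0.4)])


def _pyridine() -> Chem.Mol:
    coords = [(1.39 * np.cos(np.radians(60 * k)),
               1.39 * np.sin(np.radians(60 * k)), 0.0) for k in range(6)]
    return _template("c1ccncc1", coords)


_PALETTE = (_benzene, _acetate, _methylamine, _acetamide, _propane, _pyridine)


@pytest.fixture(scope="session")
def toy_ligand_factory():
    """Factory: random fragment in a random pose near (or far from) the
    pocket cavity; returns a curated LigandRecord."""

    def make(rng: np.random.Generator, far: bool = False):
        mol = Chem.Mol(_PALETTE[int(rng.integers(len(_PALETTE)))]())
        r = random_rotation(rng)
        if far:
            t = rng.uniform(40, 60, 3)
        else:
            t = np.array([rng.uniform(-9, 8), rng.uniform(-7, 5),
                          rng.uniform(-6, 7)])
        conf = mol.GetConformer()
        for i in range(mol.GetNumAtoms()):
            p = np.array(list(conf.GetAtomPosition(i)))
            conf.SetAtomPosition(i, Point3D(*(r @ p + t)))
        return record_from_mol("TOY", mol)

    return make
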