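import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from hydroqsar.fixtures import ToyComplexSpec, make_toy_complex
from hydroqsar.structure_model import from_rdkit, parameterize


def mol_from_smiles(smiles: str, seed: int = 11):
    """Embedded 3D molecule with explicit hydrogens (deterministic)."""
    mol = Chem.MolFromSmiles(smiles)
    mol = Chem.AddHs(mol)
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return from_rdkit(mol, name=smiles)


@pytest.fixture(scope="session")
def phenol_structure():
    return mol_from_smiles("c1ccccc1O")


@pytest.fixture(scope="session")
def benzene_structure():
    return mol_from_smiles("c1ccccc1")


@pytest.fixture()
def e2_like_complex():
    return make_toy_complex(ToyComplexSpec(
        ligand_template="e2_like",
        feature_switches=frozenset({"HB_E353", "HB_H524"})))


@pytest.fixture()
def parameterized_e2(e2_like_complex):
    parameterize(e2_like_complex.ligand)
    return e2_like_complex


def random_rotation(seed: int) -> np.ndarray:
    """A uniformly random proper rotation matrix (seeded)."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
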