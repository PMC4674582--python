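import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

import minimadock as md
from minimadock.io import ligand_from_rdkit
from minimadock.toys import DOUBLE_WELL_SEARCH_RADIUS


@pytest.fixture(scope="session")
def double_well():
    """Two-site pocket, single-atom probe, its grid-scan oracle minima."""
    spec = md.ToySystemSpec("double-well", ligand_size=1, n_torsions=0, seed=0)
    receptor = md.make_toy_pocket(spec)
    ligand, conf = md.make_toy_ligand(spec)
    oracle = md.grid_scan_minima(receptor, ligand)
    return receptor, ligand, conf, oracle


@pytest.fixture(scope="session")
def double_well_cfg():
    return dict(sphere_radius=DOUBLE_WELL_SEARCH_RADIUS, capacity=1024)


@pytest.fixture(scope="session")
def chain1():
    """Isolated 4-atom chain with one rotatable torsion."""
    spec = md.ToySystemSpec("none", ligand_size=4, n_torsions=1, seed=0)
    return md.make_toy_ligand(spec)


def mol_from_smiles(smiles: str, seed: int = 7) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=seed)
    return mol


@pytest.fixture(scope="session")
def butane_ligand():
    return ligand_from_rdkit(mol_from_smiles("CCCC"), "butane")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
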