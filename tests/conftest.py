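import numpy as np
import pytest

from paragrid import featurize as fz
from paragrid import network as net
from paragrid import surface as surf
from paragrid import synthdata as syn


@pytest.fixture(scope="session")
def toy_complex():
    """Small receptor/antigen pair with a two-residue interface."""
    spec = syn.ToyComplexSpec(n_receptor_residues=10, interface=(2, 5))
    return syn.make_toy_complex(spec)


@pytest.fixture(scope="session")
def toy_cloud(toy_complex):
    receptor, _, _ = toy_complex
    return surf.generate_surface(receptor)


@pytest.fixture(scope="session")
def toy_features(toy_complex):
    receptor, _, _ = toy_complex
    return fz.compute_atom_features(receptor)


@pytest.fixture(scope="session")
def abundant_complex():
    """All-interface receptor giving well over 800 positive surface points."""
    spec = syn.ToyComplexSpec(
        n_receptor_residues=48,
        n_antigen_residues=8,
        interface=tuple(range(48)),
    )
    return syn.make_toy_complex(spec)


@pytest.fixture(scope="session")
def reduced_model():
    """Untrained width-reduced network on 9-voxel grids."""
    return net.build_model(net.ModelConfig.reduced(grid_size=9), seed=0)


@pytest.fixture(scope="session")
def ala_dipeptide():
    """Ala-Ala dipeptide with embedded 3D coordinates (real chemistry fixture)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    from paragrid.structio import read_pdb_string

    mol = Chem.MolFromSequence("AA")
    mol = Chem.AddHs(mol)
    AllChem.EmbedMolecule(mol, randomSeed=7)
    return read_pdb_string(Chem.MolToPDBBlock(mol), role="receptor", name="ala2")


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
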