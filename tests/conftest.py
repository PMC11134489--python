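import pytest

from borysite import Molecule, synthesize_dataset

PHBPIN = "CC1(C)OB(OC1(C)C)c1ccccc1"


@pytest.fixture(scope="session")
def benzene():
    return Molecule.from_smiles("c1ccccc1")


@pytest.fixture(scope="session")
def pyridine():
    return Molecule.from_smiles("c1ccncc1")


@pytest.fixture(scope="session")
def thiophene():
    return Molecule.from_smiles("c1ccsc1")


@pytest.fixture(scope="session")
def indole():
    return Molecule.from_smiles("c1ccc2[nH]ccc2c1")


@pytest.fixture(scope="session")
def phbpin():
    return Molecule.from_smiles(PHBPIN)


@pytest.fixture(scope="session")
def tiny_synthetic():
    """A small deterministic rule-driven reaction set."""
    return synthesize_dataset(30, seed=11, noise=0.0)
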