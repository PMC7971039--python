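import numpy as np
import pytest

from aptapred.protein import RESIDUES, load_property_table
from aptapred.seqio import InteractionDataset, NucleotideSequence, ProteinSequence


@pytest.fixture(scope="session")
def property_table():
    return load_property_table()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_protein(rng, length):
    return "".join(rng.choice(list(RESIDUES), size=length))


@pytest.fixture
def tiny_dataset(rng):
    """Two aptamers x two proteins, three labelled pairs."""
    aptamers = {
        f"apt{i}": NucleotideSequence(id=f"apt{i}", residues=random_dna(rng, 30))
        for i in range(2)
    }
    proteins = {
        f"prot{i}": ProteinSequence(id=f"prot{i}", residues=random_protein(rng, 60))
        for i in range(2)
    }
    pairs = [("apt0", "prot0", 1), ("apt1", "prot1", 0), ("apt0", "prot1", 0)]
    return InteractionDataset(pairs=pairs, aptamers=aptamers, proteins=proteins)
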