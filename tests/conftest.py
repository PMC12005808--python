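import pytest

from purmine.normalization import default_chemical_dictionary
from purmine.synthetic import generate_corpus


@pytest.fixture(scope="session")
def chem_dict():
    return default_chemical_dictionary()


@pytest.fixture(scope="session")
def small_corpus():
    """Six synthetic articles with consistent PDB/UniProt fixtures."""
    docs, pdb, uniprot, truth = generate_corpus(6, seed=5, typo_rate=0.0)
    return docs, pdb, uniprot, truth
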