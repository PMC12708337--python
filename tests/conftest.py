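import numpy as np
import pytest

from mitocongruence.alignment import Alignment
from mitocongruence.model import ModelParams
from mitocongruence.simulate import default_mito_model, simulate_alignment
from mitocongruence.tree import PhyloTree, sample_species_tree


@pytest.fixture(scope="session")
def mito_model() -> ModelParams:
    return default_mito_model()


@pytest.fixture(scope="session")
def tree6() -> PhyloTree:
    return sample_species_tree(6, seed=11)


@pytest.fixture(scope="session")
def tree10() -> PhyloTree:
    return sample_species_tree(10, seed=13)


@pytest.fixture(scope="session")
def aln6(tree6, mito_model) -> Alignment:
    return simulate_alignment(tree6, mito_model, 300, seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
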