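import numpy as np
import pytest

from garfinder.phylo import Phylogeny, PhyloModel
from garfinder.simulate import default_model, default_roles


@pytest.fixture(scope="session")
def neutral_model() -> PhyloModel:
    return default_model()


@pytest.fixture(scope="session")
def roles():
    return default_roles()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
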