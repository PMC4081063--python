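import numpy as np
import pytest

import tbplattice as tl
from tbplattice import datasets


@pytest.fixture(scope="session")
def tata14E():
    return datasets.get_construct("tata14E")


@pytest.fixture(scope="session")
def tata14I():
    return datasets.get_construct("tata14I")


@pytest.fixture(scope="session")
def tata18I():
    return datasets.get_construct("tata18I")


@pytest.fixture(scope="session")
def tata14E_minimal():
    return datasets.get_construct("tata14E_minimal")


@pytest.fixture(scope="session")
def bend():
    return tl.BendModel()


@pytest.fixture(scope="session")
def fret_params():
    return tl.FretParameters()


@pytest.fixture(scope="session")
def energetics_50mM():
    return tl.BindingEnergetics(salt_mM=50.0)


@pytest.fixture(scope="session")
def energetics_150mM():
    return tl.BindingEnergetics(salt_mM=150.0)


@pytest.fixture(scope="session")
def conc_grid():
    return np.geomspace(0.1, 300.0, 12)
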