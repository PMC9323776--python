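import numpy as np
import pytest

from palmfiber import datasets


@pytest.fixture(scope="session")
def components():
    return datasets.load_components()


@pytest.fixture(scope="session")
def tensile_fits():
    return datasets.load_tensile_fits()


@pytest.fixture(scope="session")
def grey_table():
    return datasets.load_grey_table()


@pytest.fixture(scope="session")
def moduli(tensile_fits):
    """The 15 printed Young's moduli (MPa) in sample order."""
    return tensile_fits["e_printed"].to_numpy()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
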