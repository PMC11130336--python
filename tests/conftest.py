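import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

import phylohrm as ph


@pytest.fixture
def cherry_tree():
    return ph.parse_newick("((A:0.5,B:1.2):0.7,(C:0.3,D:0.9):1.1);")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_fixture():
    """A 150-tip clade-structured fixture shared by slower tests."""
    return ph.make_nfc_like_fixture(n_tips=150, seed=7)
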