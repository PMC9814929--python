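import numpy as np
import pytest

from oligofib.fcs import FocalVolume
from oligofib.fibril import build_fibril_lattice, build_ideal_strand


@pytest.fixture(scope="session")
def focal():
    return FocalVolume(lateral_radius=0.3)


@pytest.fixture(scope="session")
def default_lattice():
    """The 36-strand antiparallel starting lattice with builder defaults."""
    return build_fibril_lattice()


@pytest.fixture(scope="session")
def ideal_strand():
    coords, resids, names = build_ideal_strand()
    return coords, resids, names


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
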