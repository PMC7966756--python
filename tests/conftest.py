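import numpy as np
import pytest

from icebound.ice_lattice import build_ice_lattice, extract_plane_patch
from icebound.synthetic_data import gen_reference_structure


@pytest.fixture(scope="session")
def reference_structure():
    """Synthetic stand-in AFP crystal with planted motifs (746 waters)."""
    st, truth = gen_reference_structure(seed=1)
    return st, truth


@pytest.fixture(scope="session")
def variant_structure():
    """Second stand-in with the mutant-crystal water count (554)."""
    st, truth = gen_reference_structure(seed=7, n_waters_total=554)
    return st, truth


@pytest.fixture(scope="session")
def ice_lattice_default():
    return build_ice_lattice(4.52, 7.36, 4)


@pytest.fixture(scope="session")
def basal_patch(ice_lattice_default):
    return extract_plane_patch(ice_lattice_default, "basal", 1.0, min_count=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
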