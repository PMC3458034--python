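import numpy as np
import pytest

import ringmodes as rm
from ringmodes.enm import SpringNetwork, anm_decompose, gnm_decompose


@pytest.fixture(scope="session")
def c14():
    """Default noise-free 14-mer ring + ground truth."""
    return rm.build_synthetic_ring(rm.RingSpec())


@pytest.fixture(scope="session")
def c14_structure(c14):
    return c14[0]


@pytest.fixture(scope="session")
def c14_truth(c14):
    return c14[1]


@pytest.fixture(scope="session")
def c14_gnm(c14_structure):
    return gnm_decompose(SpringNetwork(c14_structure, 10.0))


@pytest.fixture(scope="session")
def c14_anm(c14_structure):
    return anm_decompose(SpringNetwork(c14_structure, 15.0, flavor="ANM"))


@pytest.fixture(scope="session")
def c14_analysis(c14_structure, c14_gnm, c14_anm):
    """Full slow-mode analysis of the default ring (reuses decompositions)."""
    return rm.analyze_ring_modes(c14_structure, gnm=c14_gnm, anm=c14_anm)


@pytest.fixture(scope="session")
def small_ring():
    """Cheap 6-mer ring (96 nodes) for oracle-grade comparisons."""
    return rm.build_synthetic_ring(
        rm.RingSpec(n_monomers=6, tm1_length=8, tm2_length=6, loop_length=2)
    )


@pytest.fixture(scope="session")
def small_structure(small_ring):
    return small_ring[0]


@pytest.fixture(scope="session")
def small_gnm(small_structure):
    return gnm_decompose(SpringNetwork(small_structure, 10.0))


@pytest.fixture(scope="session")
def fast_spec():
    """Small 8-mer spec (200 nodes) for pipeline-level tests."""
    return rm.RingSpec(n_monomers=8, tm1_length=12, tm2_length=10, loop_length=3)


def make_line_structure(points, chain_size=1, names=None):
    """Build a CoarseStructure from raw points, chains of ``chain_size``."""
    from ringmodes.structure_io import CoarseStructure, ResidueRecord

    points = np.asarray(points, dtype=float)
    records = []
    chains = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for i, p in enumerate(points):
        chain = chains[i // chain_size]
        num = i % chain_size + 1
        name = names[i] if names is not None else "ALA"
        records.append(ResidueRecord(chain, num, "", name, tuple(map(float, p))))
    n = len(points) // chain_size
    return CoarseStructure(tuple(records), n, chain_size, "constructed")


@pytest.fixture
def line3():
    """Three collinear nodes spaced 5 Å on the x axis (one chain)."""
    return make_line_structure([[0, 0, 0], [5, 0, 0], [10, 0, 0]], chain_size=3)
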