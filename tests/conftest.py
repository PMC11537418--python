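import numpy as np
import pytest

from ca1forge import atlas, fixtures


@pytest.fixture(scope="session")
def slab():
    return fixtures.make_slab(60, 16, 16, 10.0)


@pytest.fixture(scope="session")
def slab_coords(slab):
    cl = atlas.compute_centerline(slab.mask, slab.endpoints)
    field = atlas.build_coordinates(slab.mask, cl, slab.upper_shell,
                                    slab.lower_shell)
    return cl, field


@pytest.fixture(scope="session")
def annulus():
    return fixtures.make_quarter_annulus()


@pytest.fixture(scope="session")
def annulus_coords(annulus):
    cl = atlas.compute_centerline(annulus.mask, annulus.endpoints)
    field = atlas.build_coordinates(annulus.mask, cl, annulus.upper_shell,
                                    annulus.lower_shell)
    return cl, field


@pytest.fixture(scope="session")
def toy_circuit():
    return fixtures.make_toy_circuit(n_pc=25, n_int=8, n_fibers=40,
                                     seed=7)


def angles_between(a, b):
    """Pairwise angles in degrees between unit-vector arrays."""
    dots = np.clip(np.einsum("ij,ij->i", a, b), -1.0, 1.0)
    return np.degrees(np.arccos(dots))
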