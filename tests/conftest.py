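import numpy as np
import pytest

from neovb import SimulationParams, SurfaceMesh, make_sphere_mesh
from neovb.synthetic_data import make_lattice_mesh


@pytest.fixture(scope="session")
def tetra_mesh() -> SurfaceMesh:
    coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                       [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    tris = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return SurfaceMesh(coords, tris)


@pytest.fixture(scope="session")
def icosahedron() -> SurfaceMesh:
    return make_sphere_mesh(0, 1.0)


@pytest.fixture(scope="session")
def icosphere2() -> SurfaceMesh:
    """Subdivisions-2 sphere at radius 4 mm: ~1 mm edge length, the small
    simulation surface."""
    return make_sphere_mesh(2, 4.0)


@pytest.fixture(scope="session")
def lattice05() -> SurfaceMesh:
    """41 x 41 planar lattice at 0.5 mm spacing (extends 10 mm from centre)."""
    return make_lattice_mesh(41, 41, spacing=0.5)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(n_per_group=3)
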