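import numpy as np
import pytest
import trimesh

from imlen.mesh_io import TriangleMesh
from imlen.phantom import PhantomSpec, make_aorta_mesh, make_coronary_centerline


@pytest.fixture(scope="session")
def icosphere() -> TriangleMesh:
    """Unit icosphere: watertight, convex, all vertices at radius 1."""
    ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
    return TriangleMesh.from_arrays(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def icosahedron() -> TriangleMesh:
    ico = trimesh.creation.icosahedron()
    return TriangleMesh.from_arrays(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(im_length_mm=8.0)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """Default-resolution phantom shared across tests (mesh build is the
    expensive part)."""
    mesh = make_aorta_mesh(default_spec)
    centerline, truth = make_coronary_centerline(default_spec)
    return mesh, centerline, truth


@pytest.fixture(scope="session")
def coarse_spec() -> PhantomSpec:
    """A small, fast phantom for geometry unit tests."""
    return PhantomSpec(
        im_length_mm=5.0,
        aorta_radius_mm=6.0,
        aorta_height_mm=20.0,
        target_edge_mm=0.8,
        total_length_mm=15.0,
        centerline_spacing_mm=0.5,
    )


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    mesh = make_aorta_mesh(coarse_spec)
    centerline, truth = make_coronary_centerline(coarse_spec)
    return mesh, centerline, truth
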