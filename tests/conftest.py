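import numpy as np
import pytest
import trimesh

from seegplan.anatomy_io import TriMesh
from seegplan.phantom import PhantomSpec, generate_scene


def icosphere(subdivisions: int = 4, radius: float = 70.0, name: str = "sphere") -> TriMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces), name=name)


@pytest.fixture(scope="session")
def scene():
    """Default phantom scene (gently bumpy brain), shared across tests."""
    return generate_scene(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def sphere_scene():
    """Exact-sphere phantom: closed-form insertion-angle ground truth."""
    return generate_scene(PhantomSpec(seed=1, surface_bumpiness=0.0))


@pytest.fixture(scope="session")
def unit_icosphere():
    return icosphere(subdivisions=3, radius=1.0)


@pytest.fixture(scope="session")
def brain_sphere():
    return icosphere(subdivisions=4, radius=70.0, name="brain")
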