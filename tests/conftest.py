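import numpy as np
import pytest
import trimesh

from craniotome import PhantomConfig, TriangleMesh, generate_phantom


@pytest.fixture(scope="session")
def default_scene():
    """Full-resolution phantom shared by read-only tests."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def small_scene():
    """Coarse phantom for tests that mutate or iterate heavily."""
    return generate_phantom(PhantomConfig(subdivision_level=3, seed=1))


@pytest.fixture
def cube_mesh():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces), name="cube")


@pytest.fixture
def icosphere():
    def make(subdivisions: int = 3, radius: float = 85.0) -> TriangleMesh:
        s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
        return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces), name="sphere")

    return make
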