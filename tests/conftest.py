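import numpy as np
import pytest

from neuroroi.datasets import default_head_model
from neuroroi.headmodel import CorticalMesh, make_cortical_mesh


@pytest.fixture(scope="session")
def head():
    """Default desk-scale head model: 642-vertex cortex, 32-channel cap."""
    return default_head_model()


@pytest.fixture(scope="session")
def small_head():
    """Smaller head model (162 vertices) for cheap solver tests."""
    return default_head_model(n_subdivisions=2)


@pytest.fixture(scope="session")
def mesh1():
    return make_cortical_mesh(1, 80.0)


@pytest.fixture(scope="session")
def mesh2():
    return make_cortical_mesh(2, 80.0)


@pytest.fixture(scope="session")
def triangle_mesh():
    """Single triangle: the complete graph K3 as a degenerate mesh."""
    verts = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return CorticalMesh(vertices=verts, faces=np.array([[0, 1, 2]]),
                        normals=normals)
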