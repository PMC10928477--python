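import numpy as np
import pytest
import trimesh

from spinesim.geometry import SpineMesh, build_initial_spine


@pytest.fixture(scope="session")
def icosphere():
    """Unit icosphere, 3 subdivisions (well-resolved discrete sphere)."""
    ico = trimesh.creation.icosphere(3)
    return SpineMesh(ico.vertices.copy(), ico.faces.copy())


@pytest.fixture(scope="session")
def icosphere_coarse():
    ico = trimesh.creation.icosphere(2)
    return SpineMesh(ico.vertices.copy(), ico.faces.copy())


@pytest.fixture(scope="session")
def spine():
    """Default initial spine mesh (head R=0.25 at z=0.85, neck r=0.1)."""
    return build_initial_spine()


@pytest.fixture(scope="session")
def spine_coarse():
    return build_initial_spine(target_edge=0.08)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
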