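import numpy as np
import pytest

from orthofem.fem import RegionStiffnessCache
from orthofem.materials import homogeneous_materials
from orthofem.phantom import PhantomConfig, build_phantom, place_landmarks


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def default_mesh(default_config):
    return build_phantom(default_config)


@pytest.fixture(scope="session")
def default_landmarks(default_mesh):
    return place_landmarks(default_mesh)


@pytest.fixture(scope="session")
def h_cache(default_mesh):
    """Region-wise stiffness cache reused across solver tests."""
    return RegionStiffnessCache.for_materials(default_mesh, homogeneous_materials())


@pytest.fixture(scope="session")
def mirror_index(default_mesh):
    """Node index map of the midsagittal reflection x -> -x."""
    key = {tuple(np.round(c, 9)): i for i, c in enumerate(default_mesh.nodes)}
    return np.array(
        [key[tuple(np.round([-c[0], c[1], c[2]], 9))] for c in default_mesh.nodes]
    )
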