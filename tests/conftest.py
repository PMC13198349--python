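import numpy as np
import pytest
import trimesh

from lpmsim.mesh_io import TriangleMesh
from lpmsim.pipeline import make_fixtures
from lpmsim.synthetic_anatomy import AnatomyConfig, generate_ed_scene, generate_patient


def rigid_transform(seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic random rotation matrix and translation vector."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    rot = trimesh.transformations.quaternion_matrix(q)[:3, :3]
    return rot, rng.uniform(-30, 30, 3)


def unit_cube_mesh(side: float = 1.0, label=None) -> TriangleMesh:
    tm = trimesh.creation.box(extents=(side, side, side))
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces), label)


@pytest.fixture(scope="session")
def default_config() -> AnatomyConfig:
    return AnatomyConfig()


@pytest.fixture(scope="session")
def default_ed(default_config):
    return generate_ed_scene(default_config)


@pytest.fixture(scope="session")
def default_patient(default_config):
    return generate_patient(default_config)


@pytest.fixture(scope="session")
def micro_fixtures():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def coarse_config() -> AnatomyConfig:
    """Low-resolution anatomy for fast engine tests."""
    return AnatomyConfig(n_circ=16, n_long=8)
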