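import numpy as np
import pytest
import trimesh

from zygoplan.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240919)


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse noiseless phantom shared by read-only tests."""
    return generate_phantom(PhantomParams(mesh_resolution_mm=2.0, seed=3))


@pytest.fixture(scope="session")
def default_phantom():
    """Default-resolution noiseless phantom (the study conditions)."""
    return generate_phantom(PhantomParams(seed=11))


@pytest.fixture()
def unit_sphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)


def random_rigid(rng):
    """A uniformly random proper rotation + bounded translation."""
    from scipy.spatial.transform import Rotation

    from zygoplan.geometry import RigidTransform

    q = rng.normal(size=4)
    R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    if np.linalg.det(R) < 0:  # quaternions always give det +1, but be safe
        R = -R
    return RigidTransform(R, rng.uniform(-10, 10, size=3))
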