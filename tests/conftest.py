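import numpy as np
import pytest

from headalign import PhantomSpec, generate_phantom
from headalign.landmarks import LandmarkSet


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    """One generated phantom shared across tests (volume, landmarks, labels)."""
    return generate_phantom(phantom_spec)


@pytest.fixture(scope="session")
def small_grid():
    """A small 1 mm isotropic grid for cheap voxel-level tests."""
    from headalign import VolumeGrid

    return VolumeGrid(
        voxels=np.zeros((40, 40, 40), dtype=np.float32),
        spacing=np.ones(3),
        origin=np.zeros(3),
    )


def random_landmarks(rng: np.random.Generator) -> LandmarkSet:
    """Anatomically plausible random landmark geometry for property tests."""
    mid = rng.uniform(-20, 20, size=3)
    sep = rng.uniform(50, 70)
    anterior = rng.uniform(60, 100)
    superior = rng.uniform(-20, 20)
    rc = mid + np.array([-sep / 2, 0, 0]) + rng.uniform(-3, 3, size=3)
    lc = mid + np.array([+sep / 2, 0, 0]) + rng.uniform(-3, 3, size=3)
    nb = mid + np.array([0.0, -anterior, superior]) + rng.uniform(-3, 3, size=3)
    return LandmarkSet(right_cochlea=rc, left_cochlea=lc, nasal_bridge=nb)
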