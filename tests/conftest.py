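import numpy as np
import pytest

from faceasym import synthetic


@pytest.fixture(scope="session")
def base_case():
    """Symmetric synthetic face at the default working resolution."""
    return synthetic.generate_base_face(resolution=40, seed=0)


@pytest.fixture(scope="session")
def small_case():
    """Coarser symmetric face for registration-heavy tests."""
    return synthetic.generate_base_face(resolution=20, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid(rng):
    """A uniformly random proper rotation + bounded translation."""
    from scipy.spatial.transform import Rotation

    from faceasym.pose import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return RigidTransform(R, t)
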