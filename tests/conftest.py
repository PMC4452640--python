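import numpy as np
import pytest

from gliomri.dsc import DSCAcquisition
from gliomri.dti import default_scheme
from gliomri.phantom import PhantomGeometry, default_effects, make_truth


@pytest.fixture(scope="session")
def effects():
    return default_effects()


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced grid for tests that do not need the full acquisition matrix."""
    return PhantomGeometry(matrix=(48, 48, 3), brain_radius_mm=6.0,
                           tumour_centre_mm=(2.5, 0.5, 0.0),
                           tumour_radius_mm=2.0)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def acq():
    return DSCAcquisition()


@pytest.fixture(scope="session")
def truth_male_tumour(small_geometry, effects):
    return make_truth(small_geometry, effects, "male/tumour", seed=1)


def random_psd_tensors(n: int, seed: int = 0) -> np.ndarray:
    """Random symmetric positive semi-definite 3x3 tensors (um^2/s scale)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, 3, 3))
    return 500.0 * np.einsum("nij,nkj->nik", a, a)
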