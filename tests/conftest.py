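import numpy as np
import pytest

from neuritemap import default_scheme


@pytest.fixture(scope="session")
def scheme():
    """The default 54-measurement multi-shell scheme."""
    return default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20110701)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
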