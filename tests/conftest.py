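import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_grid():
    from emalign_kit.so3 import candidate_grid

    return candidate_grid()


@pytest.fixture(scope="session")
def phantom48():
    from emalign_kit.fixtures import PhantomSpec, make_phantom

    return make_phantom(PhantomSpec(n=48, seed=3))


@pytest.fixture(scope="session")
def phantom32():
    from emalign_kit.fixtures import PhantomSpec, make_phantom

    return make_phantom(PhantomSpec(n=32, seed=5))


def blob_map(n, centers, sigma):
    """Isotropic-Gaussian test volume on the package's centered grid."""
    x = np.arange(n) - n // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    out = np.zeros((n, n, n))
    for c in centers:
        out += np.exp(-((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) / (2 * sigma**2))
    return out
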