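import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def flat_grid_pair():
    """Two registered scans of one patient: uniform thickness 1.2 / 1.5 mm."""
    from plaqueprog import build_cylinder_grid

    radii = np.array([4.0, 4.0, 3.6, 3.2, 3.2])
    base = build_cylinder_grid("P1", 1, 2, 2, radii, np.full((5, 100), 1.2))
    follow = build_cylinder_grid("P1", 2, 2, 2, radii, np.full((5, 100), 1.5))
    return base, follow


@pytest.fixture
def spatial_dataset(rng):
    """Mid-size synthetic single-patient regression data with known slope."""
    from plaqueprog import sample_spatial_gaussian

    n = 150
    coords = rng.uniform(0, 16, (n, 3))
    x = rng.normal(50.0, 10.0, n)
    y = 0.1 + 0.002 * x + sample_spatial_gaussian(coords, 0.7, 0.04, rng)
    return coords, x, y
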