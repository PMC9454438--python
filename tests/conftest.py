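import numpy as np
import pytest

from hipcongruency.geometry import CircleSpec, Point2D, circle_polygon
from hipcongruency.synthetic import CohortSpec, HipShapeParams, make_cohort, make_hip


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_simple_polygon(rng, n_max=24):
    """A random star-shaped (hence simple) polygon around a random center."""
    n = int(rng.integers(4, n_max))
    center = rng.uniform(-50, 50, size=2)
    # n arc increments tiling the full circle: vertices in strictly
    # increasing polar angle about the center, star-shaped, hence simple
    gaps = rng.uniform(0.1, 1.0, size=n)
    angles = 2 * np.pi * (np.cumsum(gaps) - gaps[0]) / gaps.sum()
    radii = rng.uniform(1.0, 30.0, size=n)
    from hipcongruency.geometry import Polygon2D

    xy = np.column_stack(
        (center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles))
    )
    return Polygon2D(xy)


@pytest.fixture
def unit_square():
    from hipcongruency.geometry import Polygon2D

    return Polygon2D([(0, 0), (1, 0), (1, 1), (0, 1)])


@pytest.fixture
def synthetic_hip():
    """One clean synthetic hip with mild subluxation."""
    return make_hip(HipShapeParams(lateral_displacement=10.0), oracle_resolution=400)


@pytest.fixture(scope="session")
def small_cohort():
    """20-hip cohort, low oracle resolution, shared across tests."""
    spec = CohortSpec(grade_counts={g: 4 for g in "ABCDE"}, oracle_resolution=300, seed=7)
    return make_cohort(spec)


def disc_polygon(cx, cy, r, n=256):
    return circle_polygon(CircleSpec(Point2D(cx, cy), r), n)
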