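import numpy as np
import pytest

from navphantom import (
    FiducialSet,
    Frame,
    NoiseModel,
    PhantomParams,
    Unit,
    generate_case,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240896)


@pytest.fixture
def random_points(rng):
    """Seven well-spread points, roughly head-sized (mm)."""
    return rng.uniform(-80.0, 80.0, size=(7, 3))


def make_set(points, labels=None, **kw):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = tuple(labels) if labels is not None else tuple(
        range(1, len(points) + 1)
    )
    kw.setdefault("frame", Frame.RICS)
    kw.setdefault("units", Unit.MM)
    return FiducialSet(points=points, labels=labels, **kw)


@pytest.fixture
def small_params():
    """Phantom parameters with a small lesion, for fast case generation."""
    return PhantomParams(lesion_volume_range=(8.0, 10.0))


@pytest.fixture
def noiseless():
    return NoiseModel(sigma_probe=0.0, rot_sigma_deg=0.0, trans_sigma=0.0)


@pytest.fixture
def default_case(small_params):
    return generate_case(small_params, seed=42)
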