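import numpy as np
import pytest

from eogcal import AffineParams, DistortionSpec, GazeDataset, make_simulation_pattern, make_target_grid


@pytest.fixture
def grid():
    """Default radial 24-point target grid (8 directions x 3 eccentricities)."""
    return make_target_grid()


@pytest.fixture
def identity_dataset(grid):
    """Gazing data where raw coordinates already equal the targets."""
    return GazeDataset(targets=grid.points.copy(), raw=grid.points.copy(), labels=list(grid.labels))


@pytest.fixture
def example_distortion():
    """A full distortion exercising every transform component."""
    return DistortionSpec(
        pattern="d",
        scales=(0.8, 1.3, 1.1, 0.9),
        rotation=np.radians(20.0),
        shear=(0.15, -0.10),
        translation=(40.0, -25.0),
    )


def random_affine_params(rng) -> AffineParams:
    """Draw model parameters from the declared simulation ranges."""
    return AffineParams(
        tx=rng.uniform(-100, 100),
        ty=rng.uniform(-100, 100),
        m1=rng.uniform(-0.5, 0.5),
        m2=rng.uniform(-0.5, 0.5),
        theta=rng.uniform(-np.pi / 3, np.pi / 3),
        s1=rng.uniform(0.5, 2.0),
        s2=rng.uniform(0.5, 2.0),
        s3=rng.uniform(0.5, 2.0),
        s4=rng.uniform(0.5, 2.0),
    )
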