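import numpy as np
import pytest

from slicocc import Ellipsoid, PhantomSpec, simulate_study


def small_spec(**overrides) -> PhantomSpec:
    """Half-scale phantom (32^3, ~13k brain voxels) for fast unit tests."""
    kwargs = dict(
        grid_shape=(32, 32, 32),
        brain_region=Ellipsoid((15.75, 15.75, 15.75), (15.0, 15.0, 14.5)),
        hotspot_regions=[
            ("caudate", Ellipsoid((11.0, 17.0, 20.0), (3.5, 4.0, 3.5)), 25.0),
            ("caudate", Ellipsoid((20.5, 17.0, 20.0), (3.5, 4.0, 3.5)), 25.0),
            ("putamen", Ellipsoid((8.0, 15.0, 12.0), (3.0, 4.0, 4.0)), 50.0),
            ("putamen", Ellipsoid((23.5, 15.0, 12.0), (3.0, 4.0, 4.0)), 50.0),
        ],
        seed=7,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    spec = small_spec()
    truth, stages = simulate_study(spec, return_stages=True)
    return spec, truth, stages


@pytest.fixture(scope="session")
def small_series(small_phantom):
    _, _, stages = small_phantom
    return stages["smoothed"]


@pytest.fixture(scope="session")
def noiseless_small():
    """Noise-free, unsmoothed half-scale study (ideal series)."""
    spec = small_spec(noise_slope=0.0, noise_intercept=0.0, sigma_gauss_voxels=0.0)
    truth, series = simulate_study(spec)
    return spec, truth, series


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
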