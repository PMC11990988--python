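import numpy as np
import pytest

import projprof as pp


@pytest.fixture(scope="session")
def small_spec() -> pp.SimulationSpec:
    """Three well-separated compounds on an 8-minute run, band centers on the
    4-nm wavelength grid so the projection can reach each true lambda_max."""
    return pp.SimulationSpec(
        compounds=[
            pp.CompoundSpec(2.0, 150.0, 0.05, 0.01, [(212.0, 8.0, 1.0)], "a"),
            pp.CompoundSpec(4.5, 80.0, 0.06, 0.02, [(252.0, 10.0, 1.0)], "b"),
            pp.CompoundSpec(6.5, 200.0, 0.07, 0.0, [(228.0, 9.0, 1.0)], "c"),
        ],
        time_span=(0.0, 8.0),
        sampling_rate=2.5,
        wavelength_range=(200.0, 320.0, 4.0),
        noise_sd=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cube(small_spec):
    return pp.simulate_cube(small_spec)


@pytest.fixture(scope="session")
def small_noise_windows():
    """Peak-free windows of the small cube's time axis."""
    return ((0.5, 1.0), (3.0, 3.5), (7.5, 8.0))


@pytest.fixture(scope="session")
def corrected_small_cube(small_cube):
    cube, _ = small_cube
    corrected, baseline = pp.correct_cube(cube, pp.default_params("ALS"))
    return corrected, baseline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
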