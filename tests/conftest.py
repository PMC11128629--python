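import numpy as np
import pytest

from canspec import NoiseModelParams, make_array_spec, make_freq_grid


@pytest.fixture(scope="session")
def small_spec():
    """A quarter-pitch sensor grid small enough for fast simulation."""
    return make_array_spec(64, 96, 6.5, 5.6)


@pytest.fixture(scope="session")
def freq_grid():
    return make_freq_grid()


@pytest.fixture(scope="session")
def default_params():
    return NoiseModelParams()


@pytest.fixture(scope="session")
def exact_params():
    """Noise model without estimator sampling: PSDs equal the model exactly."""
    return NoiseModelParams(estimator_averages=0, sensor_variability=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
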