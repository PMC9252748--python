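import numpy as np
import pytest

from thermosvd import (
    AxisKind,
    ModelSpec,
    Scheme,
    SpectralMatrix,
    ThermoParams,
    load_preset,
    simulate_scan_spectra,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def rank1_matrix():
    """X = a b^T with known factors, on a temperature axis."""
    lam = np.linspace(300, 400, 11)
    temps = np.linspace(20, 70, 6)
    a = np.exp(-0.5 * ((lam - 340) / 20) ** 2) + 0.1
    b = 1.0 / (1.0 + np.exp((temps - 45) / 5))
    sm = SpectralMatrix(lam, temps, np.outer(a, b), axis_kind=AxisKind.TEMPERATURE_SCAN)
    return sm, a, b


@pytest.fixture
def random_matrix(rng):
    lam = np.arange(300, 306.0)
    temps = np.linspace(20, 60, 5)
    X = rng.normal(size=(6, 5))
    return SpectralMatrix(lam, temps, X, axis_kind=AxisKind.TEMPERATURE_SCAN)


@pytest.fixture(scope="session")
def two_state_spec():
    return load_preset("two_state_fluor", seed=11)


@pytest.fixture(scope="session")
def three_state_spec():
    return load_preset("three_state_hidden_intermediate", seed=11)


@pytest.fixture(scope="session")
def three_state_noise_free():
    return load_preset("three_state_hidden_intermediate", seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def two_state_model():
    return ModelSpec(Scheme.TWO_STATE_REV)


@pytest.fixture(scope="session")
def two_state_params():
    return ThermoParams(tm1=50.0, dh1=400.0)
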