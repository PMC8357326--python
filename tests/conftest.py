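import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from fiberspec.calibration import run_calibration_sequence
from fiberspec.scenarios import simulate_calibration_measurements
from fiberspec.simulate import default_model, noise_free
from fiberspec.spectra import Spectrum, WavelengthGrid, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_grid():
    """A cheap 101-point grid for arithmetic-level tests."""
    return WavelengthGrid(np.linspace(400.0, 800.0, 101))


@pytest.fixture(scope="session")
def model(grid):
    return default_model(grid, seed=11)


@pytest.fixture(scope="session")
def ideal_model(grid):
    """Read noise and speckle disabled: the algebraically exact instrument."""
    return noise_free(default_model(grid, seed=11))


@pytest.fixture(scope="session")
def ideal_calibration(ideal_model):
    meas = simulate_calibration_measurements(
        ideal_model, n_locations=2, background_excess=1.0
    )
    return run_calibration_sequence(meas)


@pytest.fixture(scope="session")
def clinic_calibration(model):
    """Default-noise calibration with full 20-location speckle averaging."""
    meas = simulate_calibration_measurements(model, n_locations=20)
    return run_calibration_sequence(meas)


def make_spectrum(grid, values, units="counts"):
    return Spectrum(grid, np.asarray(values, dtype=float), units)
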