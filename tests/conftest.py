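import numpy as np
import pytest

from savehsi.calibration import calibrate
from savehsi.colorspace import WavelengthGrid, cie_1931_cmf
from savehsi.synthetic import (
    daylight_illuminant,
    gaussian_rgb_camera,
    ideal_srgb_camera,
    make_checker_measurements,
    make_color_checker,
    make_polynomial_checker,
    reference_nbi_light,
    stack_spectra,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def cmf(grid):
    return cie_1931_cmf(grid)


@pytest.fixture(scope="session")
def wli_light(grid):
    return daylight_illuminant(grid)


@pytest.fixture(scope="session")
def nbi_light(grid):
    return reference_nbi_light(grid)


@pytest.fixture(scope="session")
def checker(grid):
    return make_color_checker(0, grid=grid)


@pytest.fixture(scope="session")
def checker_values(checker):
    return stack_spectra(checker)


@pytest.fixture(scope="session")
def camera(grid, wli_light):
    """Noiseless quantising physical-style camera."""
    return gaussian_rgb_camera(grid, wli_light, seed=0)


@pytest.fixture(scope="session")
def exact_camera(grid, cmf, wli_light):
    """Noiseless, unquantised colorimetric camera (exact XYZ decode)."""
    return ideal_srgb_camera(grid, cmf, wli_light, quantize=False)


@pytest.fixture(scope="session")
def measurements(camera, wli_light, cmf):
    return make_checker_measurements(0, camera, wli_light, cmf)


@pytest.fixture(scope="session")
def model(measurements, wli_light, cmf):
    return calibrate(measurements, wli_light, cmf)


@pytest.fixture(scope="session")
def exact_measurements(grid, exact_camera, wli_light, cmf):
    poly = make_polynomial_checker(0, grid, wli_light, cmf)
    return make_checker_measurements(0, exact_camera, wli_light, cmf, checker=poly)


@pytest.fixture(scope="session")
def exact_model(exact_measurements, wli_light, cmf):
    return calibrate(exact_measurements, wli_light, cmf)
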