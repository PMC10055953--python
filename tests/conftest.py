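import numpy as np
import pytest

from visnir.instrument import MockSpectrometerSpec, SampleOpticalModel, perform_calibration
from visnir.spectra import (
    INTENSITY,
    CalibrationSet,
    Spectrum,
    WavelengthGrid,
)
from visnir.synthetic import teflon_sample


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.array([500.0, 510.0, 520.0, 530.0, 540.0]))


@pytest.fixture
def simple_calib(small_grid):
    """Noise-free calibration pair: dark=10, reference=110 at every pixel."""
    dark = Spectrum(small_grid, np.full(5, 10.0), INTENSITY,
                    meta={"integration_time_ms": 100.0, "lamp_on": False})
    ref = Spectrum(small_grid, np.full(5, 110.0), INTENSITY,
                   meta={"integration_time_ms": 100.0, "lamp_on": True})
    return CalibrationSet(dark, ref, reference_integration_time_ms=100.0)


def flat_sample(reflectance: float) -> SampleOpticalModel:
    return SampleOpticalModel(
        lambda lam, r=reflectance: np.full(np.asarray(lam, float).shape, r),
        descriptor={"reflectance": reflectance})


@pytest.fixture
def noiseless_vis_spec():
    """VIS mock spectrometer with all noise switched off."""
    return MockSpectrometerSpec.default_vis(read_noise_sd=0.0,
                                            shot_noise_scale=0.0)


@pytest.fixture
def vis_spec():
    return MockSpectrometerSpec.default_vis()


@pytest.fixture
def vis_calib(vis_spec):
    return perform_calibration(vis_spec, teflon_sample(), it=100.0, n_avg=10,
                               seed=1234)


@pytest.fixture
def noiseless_vis_calib(noiseless_vis_spec):
    return perform_calibration(noiseless_vis_spec, teflon_sample(), it=100.0,
                               n_avg=1, seed=0)
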