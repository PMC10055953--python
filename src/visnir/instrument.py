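"""Mock spectrometer and the measurement / calibration procedures.

The mock spectrometer is a forward model of a grating spectrometer with a
linear detector: per pixel the expected count is

    dark_offset + dark_current * it + lamp_on * responsivity(lambda)
                                              * true_reflectance(lambda) * it

with Gaussian read noise and a signal-proportional shot-like noise term, both
clipped to [0, saturation_count].  ``responsivity`` absorbs the lamp spectral
profile (a smooth tungsten-like curve peaking in the NIR).

On top of the forward model sit the field procedures:

1. probe measurement at a typical integration time,
2. saturation check,
3. integration-time optimisation
   ``it_opt = min(0.90 * typical_it / max(reflectance), 5 s)``,
4. final acquisition at ``it_opt`` with a per-measurement dark spectrum,

plus the dark/Teflon calibration routine that produces a
:class:`~visnir.spectra.CalibrationSet`.

Reflectance during the procedures: reference spectra are recorded at the
calibration integration time, so before applying the calibration ratio the
dark-corrected reference signal is scaled linearly by the ratio of integration
times (the detector is linear in integration time by construction).  The raw,
unrescaled ratio against the stored reference is what the 0.90 safety factor
keeps just below 1; the rescaled ratio is the physical reflectance stored in
the measurement record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .spectra import (
    INTENSITY,
    CalibrationSet,
    Spectrum,
    SpectrumError,
    WavelengthGrid,
    compute_reflectance,
)

#: Empiric safety factor applied to the optimal integration time so the
#: brightest pixel stays just below the reference level.
DEFAULT_OPTIMIZER_FACTOR = 0.90
#: Hard cap on the optimised integration time, ms (avoids both very long
#: measurements and sensor saturation).
DEFAULT_OPTIMIZER_CAP_MS = 5000.0
#: Default number of averaged spectra per measurement.
DEFAULT_N_AVERAGES = 10
#: Default probe ("typical") integration time, ms.
DEFAULT_TYPICAL_IT_MS = 100.0


class AcquisitionError(RuntimeError):
    """Raised when a measurement procedure cannot produce a valid result."""


def _planck_lambda(wavelength_nm: np.ndarray, temperature_k: float) -> np.ndarray:
    """Spectral radiance shape of a blackbody, arbitrary units."""
    lam = wavelength_nm * 1e-9
    c2 = 1.4388e-2  # m K
    return lam ** -5 / np.expm1(c2 / (lam * temperature_k))


def tungsten_lamp_profile(wavelengths_nm: np.ndarray,
                          temperature_k: float = 2850.0) -> np.ndarray:
    """Smooth tungsten-halogen-like lamp profile, normalised to peak 1."""
    shape = _planck_lambda(np.asarray(wavelengths_nm, float), temperature_k)
    return shape / shape.max()


@dataclass(eq=False)
class MockSpectrometerSpec:
    """Detector physics of one mock spectrometer channel."""

    grid: WavelengthGrid
    dark_offset: float = 500.0            # counts
    dark_current: float = 0.5             # counts / ms
    responsivity: np.ndarray | None = None  # counts / (ms * reflectance unit)
    saturation_count: float = 65535.0
    read_noise_sd: float = 10.0           # counts
    shot_noise_scale: float = 1.0         # noise variance = scale^2 * signal
    max_integration_time_ms: float = 10000.0
    device_id: str = "mock"

    def __post_init__(self) -> None:
        if self.responsivity is None:
            self.responsivity = 480.0 * tungsten_lamp_profile(self.grid.wavelengths)
        self.responsivity = np.asarray(self.responsivity, dtype=float)
        if self.responsivity.shape != self.grid.wavelengths.shape:
            raise SpectrumError("responsivity must match the grid")
        if np.any(self.responsivity < 0):
            raise SpectrumError("responsivity must be >= 0")
        if self.saturation_count <= self.dark_offset:
            raise SpectrumError("saturation_count must exceed dark_offset")
        if self.max_integration_time_ms <= 0:
            raise SpectrumError("max_integration_time_ms must be > 0")

    @classmethod
    def default_vis(cls, **kw) -> "MockSpectrometerSpec":
        """Si-array VIS channel: 445-1061 nm at 2 nm/pixel."""
        grid = WavelengthGrid(np.arange(445.0, 1062.0, 2.0))
        kw.setdefault("device_id", "vis")
        return cls(grid=grid, **kw)

    @classmethod
    def default_nir(cls, **kw) -> "MockSpectrometerSpec":
        """InGaAs NIR channel: 877-1689 nm at 8.2 nm/pixel."""
        grid = WavelengthGrid(np.arange(877.0, 1693.0, 8.2))
        kw.setdefault("device_id", "nir")
        kw.setdefault("read_noise_sd", 15.0)
        return cls(grid=grid, **kw)


@dataclass(eq=False)
class SampleOpticalModel:
    """Ground-truth optical profile of a sample for the simulator.

    ``true_reflectance`` maps wavelengths (nm, vectorised) into (0, 1].
    ``descriptor`` is bookkeeping (e.g. brix, storage day).
    """

    true_reflectance: Callable[[np.ndarray], np.ndarray]
    descriptor: dict = field(default_factory=dict)

    def reflectance_on(self, grid: WavelengthGrid) -> np.ndarray:
        r = np.asarray(self.true_reflectance(grid.wavelengths), dtype=float)
        if np.any(r <= 0) or np.any(r > 1):
            raise SpectrumError("true reflectance must lie in (0, 1] on the grid")
        return r


@dataclass(eq=False)
class MeasurementRecord:
    """Result of one full measurement procedure (JSON-serialisable)."""

    sample_id: str
    device_id: str
    it_opt_ms: float
    n_averages: int
    raw_intensity: Spectrum
    dark: Spectrum
    reflectance: Spectrum
    timestamp: str | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementRecord):
            return NotImplemented
        return (self.sample_id == other.sample_id
                and self.device_id == other.device_id
                and self.it_opt_ms == other.it_opt_ms
                and self.n_averages == other.n_averages
                and self.raw_intensity == other.raw_intensity
                and self.dark == other.dark
                and self.reflectance == other.reflectance
                and self.timestamp == other.timestamp)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_acquisition(spec: MockSpectrometerSpec,
                         sample: SampleOpticalModel | None,
                         lamp_on: bool,
                         it: float,
                         n_avg: int = 1,
                         seed=None) -> Spectrum:
    """Simulate one (averaged) detector readout.

    Each of the ``n_avg`` readouts draws per-pixel Gaussian noise with
    variance ``read_noise_sd**2 + shot_noise_scale**2 * expected_signal`` and
    is clipped to ``[0, saturation_count]``; the returned spectrum is their
    mean.  Deterministic under ``seed``.
    """
    if it <= 0:
        raise AcquisitionError(f"integration time must be > 0 (got {it} ms)")
    if it > spec.max_integration_time_ms:
        raise AcquisitionError(
            f"integration time {it} ms exceeds the maximum "
            f"{spec.max_integration_time_ms} ms")
    if n_avg < 1:
        raise AcquisitionError("n_avg must be >= 1")
    rng = _rng(seed)
    expected = spec.dark_offset + spec.dark_current * it
    if lamp_on:
        if sample is None:
            raise AcquisitionError("lamp-on acquisition requires a sample model")
        expected = expected + spec.responsivity * sample.reflectance_on(spec.grid) * it
    expected = np.broadcast_to(expected, spec.grid.wavelengths.shape)
    noise_sd = np.sqrt(spec.read_noise_sd ** 2
                       + spec.shot_noise_scale ** 2 * np.maximum(expected, 0.0))
    draws = expected[None, :] + rng.normal(size=(n_avg, len(spec.grid))) * noise_sd
    draws = np.clip(draws, 0.0, spec.saturation_count)
    values = draws.mean(axis=0)
    meta = {"integration_time_ms": float(it), "n_averages": int(n_avg),
            "device_id": spec.device_id, "lamp_on": bool(lamp_on)}
    return Spectrum(spec.grid, values, INTENSITY, meta=meta)


def is_saturated(s: Spectrum, spec: MockSpectrometerSpec) -> bool:
    """True iff any valid pixel sits at or above the saturation count."""
    if s.kind != INTENSITY:
        raise SpectrumError("saturation check requires an intensity spectrum")
    if not s.valid.any():
        raise SpectrumError("saturation check on empty valid-pixel set")
    return bool(np.any(s.values[s.valid] >= spec.saturation_count))


def calibrated_reflectance(intensity: Spectrum, dark: Spectrum,
                           calib: CalibrationSet, it: float,
                           rescale: bool = True) -> Spectrum:
    """Calibration ratio with optional integration-time rescaling.

    With ``rescale=True`` the dark-corrected reference signal is scaled by
    ``it / reference_integration_time`` before applying the ratio, giving the
    physical (integration-time-invariant) reflectance.  With ``rescale=False``
    the raw ratio against the stored reference is returned (the quantity the
    integration-time optimiser drives towards 0.90).
    """
    if intensity.grid != calib.grid or dark.grid != calib.grid:
        raise SpectrumError("intensity/dark and calibration grids differ")
    scale = it / calib.reference_integration_time_ms if rescale else 1.0
    denom = (calib.reference.values - calib.dark.values) * scale
    valid = intensity.valid & dark.valid & calib.usable
    if not valid.any():
        raise SpectrumError("no valid pixels for reflectance computation")
    values = np.zeros_like(intensity.values)
    values[valid] = (intensity.values[valid] - dark.values[valid]) / denom[valid]
    meta = dict(intensity.meta)
    meta["it_rescaled"] = bool(rescale)
    return Spectrum(intensity.grid, values, "reflectance", valid, meta)


def perform_calibration(spec: MockSpectrometerSpec,
                        teflon: SampleOpticalModel,
                        it: float = DEFAULT_TYPICAL_IT_MS,
                        n_avg: int = DEFAULT_N_AVERAGES,
                        seed=None) -> CalibrationSet:
    """Record the dark (lamp off) and Teflon reference (lamp on) spectra.

    Both acquisitions use the same integration time, which is stored as the
    set's reference integration time.  A saturated reference aborts with a
    hint to use a shorter integration time.
    """
    rng = _rng(seed)
    dark = simulate_acquisition(spec, None, lamp_on=False, it=it, n_avg=n_avg,
                                seed=rng)
    reference = simulate_acquisition(spec, teflon, lamp_on=True, it=it,
                                     n_avg=n_avg, seed=rng)
    if is_saturated(reference, spec):
        raise AcquisitionError(
            "reference acquisition saturated: repeat the calibration with a "
            f"shorter integration time than {it} ms")
    return CalibrationSet(dark, reference, reference_integration_time_ms=it)


def optimize_integration_time(spec: MockSpectrometerSpec,
                              sample: SampleOpticalModel,
                              calib: CalibrationSet,
                              typical_it: float = DEFAULT_TYPICAL_IT_MS,
                              factor: float = DEFAULT_OPTIMIZER_FACTOR,
                              cap: float = DEFAULT_OPTIMIZER_CAP_MS,
                              n_avg: int = 1,
                              seed=None) -> float:
    """Find the optimal integration time for a sample.

    Probe at ``typical_it``, compute the (integration-time rescaled)
    reflectance, take its maximum ``r_max`` over valid pixels, and return
    ``min(factor * typical_it / r_max, cap)``.  A saturated probe is retried
    once at a quarter of the integration time; a second saturation or a
    non-positive ``r_max`` aborts.
    """
    rng = _rng(seed)
    it_probe = float(typical_it)
    if it_probe <= 0:
        raise AcquisitionError("typical integration time must be > 0")
    probe = simulate_acquisition(spec, sample, True, it_probe, n_avg, rng)
    if is_saturated(probe, spec):
        it_probe /= 4.0
        probe = simulate_acquisition(spec, sample, True, it_probe, n_avg, rng)
        if is_saturated(probe, spec):
            raise AcquisitionError(
                "probe measurement saturated even at a quarter of the typical "
                "integration time")
    dark = simulate_acquisition(spec, None, False, it_probe, n_avg, rng)
    refl = calibrated_reflectance(probe, dark, calib, it_probe, rescale=True)
    r_max = float(np.max(refl.values[refl.valid]))
    if r_max <= 0:
        raise AcquisitionError("no signal: maximum reflectance <= 0")
    return min(factor * it_probe / r_max, cap)


def measure_sample(spec: MockSpectrometerSpec,
                   sample: SampleOpticalModel,
                   calib: CalibrationSet,
                   typical_it: float = DEFAULT_TYPICAL_IT_MS,
                   n_avg: int = DEFAULT_N_AVERAGES,
                   seed=None,
                   sample_id: str = "sample",
                   timestamp: str | None = None) -> MeasurementRecord:
    """Full measurement procedure for one sample.

    Probe measurement, saturation check and integration-time optimisation,
    then the final averaged acquisition at ``it_opt`` together with a
    per-measurement dark spectrum; the stored reflectance is the physical
    (rescaled) calibration ratio.  Deterministic under ``seed``.
    """
    rng = _rng(seed)
    it_opt = optimize_integration_time(spec, sample, calib, typical_it,
                                       n_avg=1, seed=rng)
    it_opt = min(it_opt, spec.max_integration_time_ms)
    dark = simulate_acquisition(spec, None, False, it_opt, n_avg, rng)
    raw = simulate_acquisition(spec, sample, True, it_opt, n_avg, rng)
    if is_saturated(raw, spec):
        raise AcquisitionError(
            "final acquisition saturated; the 0.90 safety factor should "
            "prevent this — check the calibration")
    refl = calibrated_reflectance(raw, dark, calib, it_opt, rescale=True)
    refl.meta["sample_id"] = sample_id
    return MeasurementRecord(sample_id=sample_id, device_id=spec.device_id,
                             it_opt_ms=float(it_opt), n_averages=int(n_avg),
                             raw_intensity=raw, dark=dark, reflectance=refl,
                             timestamp=timestamp)
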