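"""Spectral data model and the calibration / merge transforms.

A :class:`Spectrum` is a wavelength-indexed vector of values with a kind tag
(``intensity``, ``reflectance`` or ``absorbance``), a per-pixel validity mask
and free-form acquisition metadata.  The transforms in this module implement
the dark/white-reference reflectance calibration

    reflectance = (I_sample - I_dark) / (I_teflon - I_dark)

its conversion to absorbance ``A = log10(1 / reflectance)``, wavelength-range
cropping, linear interpolation at arbitrary wavelengths, and the merging of a
VIS and a NIR absorbance spectrum at a join wavelength with an additive offset
correction applied to the NIR side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

#: Base of the logarithm used for the reflectance -> absorbance transform.
#: Decadic absorbance is the chemometrics convention.
ABSORBANCE_LOG_BASE = 10.0

#: Denominator guard for the reflectance ratio, as a fraction of the
#: reference dynamic range: pixels whose dark-corrected reference signal is
#: below this fraction of the maximum are masked invalid instead of producing
#: huge or negative reflectance values.
DENOMINATOR_GUARD_FRACTION = 1e-9

INTENSITY = "intensity"
REFLECTANCE = "reflectance"
ABSORBANCE = "absorbance"
_KINDS = (INTENSITY, REFLECTANCE, ABSORBANCE)


class SpectrumError(ValueError):
    """Raised for invalid spectral inputs (grid mismatch, empty masks, ...)."""


@dataclass(frozen=True, eq=False)
class WavelengthGrid:
    """Strictly increasing pixel-to-wavelength axis in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise SpectrumError("wavelength grid must be a non-empty 1-d array")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise SpectrumError("wavelengths must be finite and positive (nm)")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths, other.wavelengths)

    def __hash__(self):  # frozen but array-valued; identity hash is enough
        return id(self)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def contains(self, lam: float) -> bool:
        lo, hi = self.span
        return lo <= lam <= hi


@dataclass(eq=False)
class Spectrum:
    """One spectrum on a wavelength grid.

    Parameters
    ----------
    grid : WavelengthGrid
    values : ndarray, same length as the grid
    kind : {"intensity", "reflectance", "absorbance"}
    valid : bool ndarray, optional
        Per-pixel validity mask; invalid pixels are excluded from every
        downstream computation instead of raising, so one dead pixel does not
        kill a measurement.
    meta : dict
        Acquisition metadata (integration_time_ms, n_averages, device_id,
        sample_id, lamp_on, timestamp, ...).
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in _KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if self.values.ndim != 1 or len(self.values) != len(self.grid):
            raise SpectrumError("values must be 1-d and match the grid length")
        if self.valid is None:
            self.valid = np.ones(len(self.grid), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise SpectrumError("valid mask must match the grid length")
        if self.kind == INTENSITY:
            if np.any(self.values[self.valid] < 0):
                raise SpectrumError("intensity values must be >= 0")
            it = self.meta.get("integration_time_ms")
            if it is not None and it <= 0:
                raise SpectrumError("integration_time_ms must be > 0")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    valid: np.ndarray | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, kind or self.kind,
                        self.valid.copy() if valid is None else valid,
                        dict(self.meta))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (self.kind == other.kind
                and self.grid == other.grid
                and np.array_equal(self.values, other.values)
                and np.array_equal(self.valid, other.valid)
                and self.meta == other.meta)


@dataclass(eq=False)
class CalibrationSet:
    """Paired dark (lamp off) and Teflon white-reference (lamp on) spectra.

    Both are intensity spectra on one grid, recorded at
    ``reference_integration_time_ms``.  The dark-corrected reference signal
    must be positive on the declared usable pixel range.
    """

    dark: Spectrum
    reference: Spectrum
    reference_integration_time_ms: float

    def __post_init__(self) -> None:
        if self.dark.kind != INTENSITY or self.reference.kind != INTENSITY:
            raise SpectrumError("calibration spectra must be intensities")
        if self.dark.grid != self.reference.grid:
            raise SpectrumError("dark and reference must share one grid")
        if self.reference_integration_time_ms <= 0:
            raise SpectrumError("reference integration time must be > 0")
        usable = self.usable
        if not usable.any():
            raise SpectrumError(
                "reference - dark is not positive anywhere: invalid calibration")

    @property
    def grid(self) -> WavelengthGrid:
        return self.dark.grid

    @property
    def usable(self) -> np.ndarray:
        """Pixels where the dark-corrected reference signal is usable."""
        denom = self.reference.values - self.dark.values
        eps = DENOMINATOR_GUARD_FRACTION * max(float(np.max(denom)), 0.0)
        return (self.dark.valid & self.reference.valid & (denom > eps)
                & (denom > 0))


def compute_reflectance(sample: Spectrum, calib: CalibrationSet) -> Spectrum:
    """Dark/white-reference calibration of an intensity spectrum.

    Per pixel ``R = (I_sample - I_dark) / (I_teflon - I_dark)``.  Pixels whose
    denominator falls below the guard threshold are masked invalid rather than
    silently kept.
    """
    if sample.kind != INTENSITY:
        raise SpectrumError("sample must be an intensity spectrum")
    if sample.grid != calib.grid:
        raise SpectrumError("sample and calibration grids differ")
    valid = sample.valid & calib.usable
    if not valid.any():
        raise SpectrumError("all pixels invalid after calibration guard")
    denom = calib.reference.values - calib.dark.values
    values = np.zeros_like(sample.values)
    values[valid] = (sample.values[valid] - calib.dark.values[valid]) / denom[valid]
    meta = dict(sample.meta)
    return Spectrum(sample.grid, values, REFLECTANCE, valid, meta)


def to_absorbance(refl: Spectrum) -> Spectrum:
    """Transform reflectance into decadic absorbance ``A = log10(1/R)``.

    Non-positive reflectance on a valid pixel is masked with a logged warning;
    if every pixel ends up masked the spectrum is unusable and an error is
    raised.
    """
    if refl.kind != REFLECTANCE:
        raise SpectrumError("to_absorbance expects a reflectance spectrum")
    valid = refl.valid & (refl.values > 0)
    n_dropped = int(refl.valid.sum() - valid.sum())
    if n_dropped:
        logger.warning("to_absorbance: masking %d non-positive reflectance pixel(s)",
                       n_dropped)
    if not valid.any():
        raise SpectrumError("all pixels masked: no positive reflectance values")
    values = np.zeros_like(refl.values)
    values[valid] = -np.log(refl.values[valid]) / np.log(ABSORBANCE_LOG_BASE)
    return Spectrum(refl.grid, values, ABSORBANCE, valid, dict(refl.meta))


def absorbance_to_reflectance(absorb: Spectrum) -> Spectrum:
    """Inverse of :func:`to_absorbance`: ``R = 10**(-A)``."""
    if absorb.kind != ABSORBANCE:
        raise SpectrumError("expected an absorbance spectrum")
    values = np.power(ABSORBANCE_LOG_BASE, -absorb.values)
    return Spectrum(absorb.grid, values, REFLECTANCE, absorb.valid.copy(),
                    dict(absorb.meta))


def interpolate_value(s: Spectrum, lam: float) -> float:
    """Linearly interpolated value at wavelength ``lam`` (nm).

    Exact pixel hits return the stored value; interpolation uses valid pixels
    only; wavelengths outside the valid-pixel span raise.
    """
    wl = s.wavelengths[s.valid]
    vals = s.values[s.valid]
    if wl.size == 0:
        raise SpectrumError("spectrum has no valid pixels")
    if not (wl[0] <= lam <= wl[-1]):
        raise SpectrumError(
            f"wavelength {lam} nm outside valid span [{wl[0]}, {wl[-1]}] nm")
    return float(np.interp(lam, wl, vals))


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Retain exactly the pixels with ``lo <= lambda <= hi`` (metadata kept)."""
    if lo >= hi:
        raise SpectrumError(f"invalid crop range: lo={lo} >= hi={hi}")
    sel = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not sel.any():
        raise SpectrumError(f"crop [{lo}, {hi}] nm selects no pixels")
    return Spectrum(WavelengthGrid(s.wavelengths[sel]), s.values[sel],
                    s.kind, s.valid[sel], dict(s.meta))


def merge_vis_nir(vis: Spectrum, nir: Spectrum, join: float = 918.0) -> Spectrum:
    """Merge a VIS and a NIR spectrum at the join wavelength.

    The offset ``nir(join) - vis(join)`` (linearly interpolated values) is
    subtracted from every NIR value so the two curves meet at the join; the
    output grid is the VIS pixels with wavelength <= join followed by the NIR
    pixels with wavelength > join.  Both inputs must cover the join and share
    a kind; smoothing, if any, is the caller's duty beforehand.
    """
    if vis.kind != nir.kind:
        raise SpectrumError(f"kind mismatch: {vis.kind} vs {nir.kind}")
    if not (vis.grid.contains(join) and nir.grid.contains(join)):
        raise SpectrumError(f"both spectra must cover the join at {join} nm")
    offset = interpolate_value(nir, join) - interpolate_value(vis, join)
    vis_sel = vis.wavelengths <= join
    nir_sel = nir.wavelengths > join
    wl = np.concatenate([vis.wavelengths[vis_sel], nir.wavelengths[nir_sel]])
    values = np.concatenate([vis.values[vis_sel],
                             nir.values[nir_sel] - offset])
    valid = np.concatenate([vis.valid[vis_sel], nir.valid[nir_sel]])
    meta = {"merged_at_nm": join, "nir_offset": offset,
            "vis_meta": dict(vis.meta), "nir_meta": dict(nir.meta)}
    return Spectrum(WavelengthGrid(wl), values, vis.kind, valid, meta)


@dataclass(eq=False)
class SpectraDataset:
    """A set of spectra on one shared grid, with optional targets.

    ``values`` is an ``(n_samples, n_pixels)`` matrix.  ``brix`` (%Brix) and
    ``day`` (storage-day class labels) are optional per-sample targets.
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str
    sample_ids: list[str]
    brix: np.ndarray | None = None
    day: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.grid):
            raise SpectrumError("dataset columns must match the grid length")
        if len(self.sample_ids) != self.values.shape[0]:
            raise SpectrumError("one sample id per row required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SpectrumError("duplicate sample ids")
        for name in ("brix", "day"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape[0] != self.values.shape[0]:
                    raise SpectrumError(f"{name} must have one entry per sample")
                setattr(self, name, arr)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.values[i], self.kind,
                        meta={"sample_id": self.sample_ids[i]})

    def subset(self, indices) -> "SpectraDataset":
        idx = np.asarray(indices)
        return SpectraDataset(
            self.grid, self.values[idx], self.kind,
            [self.sample_ids[i] for i in idx],
            None if self.brix is None else self.brix[idx],
            None if self.day is None else self.day[idx],
            dict(self.meta))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraDataset):
            return NotImplemented
        same_targets = True
        for name in ("brix", "day"):
            a, b = getattr(self, name), getattr(other, name)
            if (a is None) != (b is None):
                same_targets = False
            elif a is not None and not np.array_equal(a, b):
                same_targets = False
        return (self.kind == other.kind and self.grid == other.grid
                and np.allclose(self.values, other.values)
                and self.sample_ids == other.sample_ids and same_targets)
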