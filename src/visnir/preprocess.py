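"""Spectral preprocessing operators and the fixed-order pipeline.

The pipeline applies, in this order and with every step individually
switchable:

1. dataset-level spectrum outlier filter (correlation to the pointwise median
   plus physical reflectance bounds),
2. reflectance -> absorbance transform,
3. Savitzky-Golay smoothing,
4. wavelength-range selection,
5. normalisation to zero by subtracting the (interpolated) value at a chosen
   wavelength,
6. Savitzky-Golay filter with derivative.

Steps 2-6 act per spectrum; only the outlier filter depends on the whole
dataset, which is why :class:`SpectralPreprocessor` learns its reference
median in ``fit`` (training data only) while ``transform`` stays row-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import (
    ABSORBANCE_LOG_BASE,
    REFLECTANCE,
    SpectraDataset,
    SpectrumError,
    Spectrum,
    interpolate_value,
)

#: Default Pearson-correlation threshold of the outlier filter.
DEFAULT_FILTER_THRESHOLD = 0.9
#: Physical reflectance bounds used by the outlier filter: values outside
#: [0, 1.2] cannot come from a diffuse-reflectance measurement of fruit
#: (a little headroom above 1 allows samples slightly brighter than Teflon).
REFLECTANCE_BOUNDS = (0.0, 1.2)


@dataclass
class SGConfig:
    """Savitzky-Golay settings: odd window, poly order, derivative order."""

    window: int
    polyorder: int
    deriv: int = 0

    def validate(self) -> None:
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError(
                f"window must be odd and > polyorder (got {self.window}/"
                f"{self.polyorder})")
        if not (0 <= self.deriv <= self.polyorder):
            raise ValueError("derivative order must satisfy 0 <= d <= polyorder")


@dataclass
class PreprocessConfig:
    """One point in the preprocessing hyperparameter space.

    ``smoothing`` and ``derivative`` are optional :class:`SGConfig` blocks
    (derivative order forced to 0 for the smoothing slot); ``range_nm``
    selects the modelling wavelength window; ``normalize_at_nm`` subtracts the
    spectrum value at that wavelength.  Disabled steps are skipped without
    reordering the pipeline.
    """

    use_filter: bool = False
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD
    use_absorbance: bool = True
    smoothing: SGConfig | None = None
    range_nm: tuple[float, float] | None = None
    normalize_at_nm: float | None = None
    derivative: SGConfig | None = None

    def validate(self) -> None:
        if self.smoothing is not None:
            if self.smoothing.deriv != 0:
                raise ValueError("the smoothing slot must use derivative order 0")
            self.smoothing.validate()
        if self.derivative is not None:
            self.derivative.validate()
        if self.range_nm is not None:
            lo, hi = self.range_nm
            if lo >= hi:
                raise ValueError(f"range lo={lo} must be < hi={hi}")
            if self.normalize_at_nm is not None and not (
                    lo <= self.normalize_at_nm <= hi):
                raise ValueError("normalize_at_nm must lie inside range_nm")

    def to_dict(self) -> dict:
        def sg(c):
            return None if c is None else {"window": c.window,
                                           "polyorder": c.polyorder,
                                           "deriv": c.deriv}
        return {"use_filter": self.use_filter,
                "filter_threshold": self.filter_threshold,
                "use_absorbance": self.use_absorbance,
                "smoothing": sg(self.smoothing),
                "range_nm": list(self.range_nm) if self.range_nm else None,
                "normalize_at_nm": self.normalize_at_nm,
                "derivative": sg(self.derivative)}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        def sg(block):
            return None if block is None else SGConfig(**block)
        cfg = cls(use_filter=d.get("use_filter", False),
                  filter_threshold=d.get("filter_threshold",
                                         DEFAULT_FILTER_THRESHOLD),
                  use_absorbance=d.get("use_absorbance", True),
                  smoothing=sg(d.get("smoothing")),
                  range_nm=tuple(d["range_nm"]) if d.get("range_nm") else None,
                  normalize_at_nm=d.get("normalize_at_nm"),
                  derivative=sg(d.get("derivative")))
        cfg.validate()
        return cfg


def savitzky_golay(values: np.ndarray, window: int, polyorder: int,
                   deriv_order: int = 0, spacing: float = 1.0) -> np.ndarray:
    """Savitzky-Golay filter: local least-squares polynomial fit per point.

    Returns the ``deriv_order``-th derivative of the local fit, scaled by the
    pixel ``spacing`` (nm) so derivatives are per-nm.  Edge points are
    evaluated from the fit polynomial of the first/last full window, so the
    output keeps the input length.  Interior points are exact for polynomial
    inputs of degree <= polyorder.
    """
    values = np.asarray(values, dtype=float)
    SGConfig(window, polyorder, deriv_order).validate()
    if values.shape[-1] < window:
        raise ValueError(
            f"window {window} larger than the spectrum ({values.shape[-1]} px)")
    return savgol_filter(values, window_length=window, polyorder=polyorder,
                         deriv=deriv_order, delta=spacing, mode="interp",
                         axis=-1)


def spectrum_outlier_filter(values: np.ndarray,
                            threshold: float = DEFAULT_FILTER_THRESHOLD,
                            reference_median: np.ndarray | None = None,
                            kind: str = REFLECTANCE,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Dataset-relative spectrum filter.

    A spectrum is flagged as an outlier if its Pearson correlation with the
    pointwise-median spectrum falls below ``threshold``, or (for reflectance
    data) if any value leaves the physical bounds [0, 1.2].  Returns
    ``(kept_indices, outlier_indices)``; deterministic.

    ``reference_median`` lets a caller reuse a median learned on training
    data (leakage-free cross-validation).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if reference_median is None:
        if values.shape[0] < 3:
            raise ValueError("outlier filter needs at least 3 spectra")
        reference_median = np.median(values, axis=0)
    med = reference_median - reference_median.mean()
    med_norm = np.linalg.norm(med)
    outlier = np.zeros(values.shape[0], dtype=bool)
    for i, row in enumerate(values):
        if kind == REFLECTANCE and (
                np.any(row < REFLECTANCE_BOUNDS[0])
                or np.any(row > REFLECTANCE_BOUNDS[1])):
            outlier[i] = True
            continue
        centered = row - row.mean()
        denom = np.linalg.norm(centered) * med_norm
        corr = float(centered @ med / denom) if denom > 0 else 0.0
        if corr < threshold:
            outlier[i] = True
    idx = np.arange(values.shape[0])
    return idx[~outlier], idx[outlier]


def normalize_at(s: Spectrum, lam: float) -> Spectrum:
    """Subtract the (interpolated) value at ``lam`` from the whole spectrum."""
    offset = interpolate_value(s, lam)
    return s.with_values(s.values - offset)


class SpectralPreprocessor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer applying the fixed-order pipeline steps 2-6.

    Operates on an ``(n_samples, n_pixels)`` matrix of reflectance values on
    the wavelength grid given at construction.  ``fit`` learns the
    pointwise-median reference of the outlier filter from the training data;
    outlier membership of any matrix is then available via
    :meth:`outlier_mask` (transform itself never drops rows, so the class
    composes with sklearn pipelines).

    Parameters mirror :class:`PreprocessConfig`; ``wavelengths`` is the shared
    grid in nm.
    """

    def __init__(self, wavelengths, *, use_filter=False,
                 filter_threshold=DEFAULT_FILTER_THRESHOLD,
                 use_absorbance=True, smoothing_window=None,
                 smoothing_polyorder=2, range_lo=None, range_hi=None,
                 normalize_at_nm=None, deriv_window=None, deriv_polyorder=2,
                 deriv_order=1):
        self.wavelengths = wavelengths
        self.use_filter = use_filter
        self.filter_threshold = filter_threshold
        self.use_absorbance = use_absorbance
        self.smoothing_window = smoothing_window
        self.smoothing_polyorder = smoothing_polyorder
        self.range_lo = range_lo
        self.range_hi = range_hi
        self.normalize_at_nm = normalize_at_nm
        self.deriv_window = deriv_window
        self.deriv_polyorder = deriv_polyorder
        self.deriv_order = deriv_order

    @classmethod
    def from_config(cls, wavelengths, config: PreprocessConfig
                    ) -> "SpectralPreprocessor":
        config.validate()
        lo, hi = config.range_nm if config.range_nm else (None, None)
        return cls(
            wavelengths,
            use_filter=config.use_filter,
            filter_threshold=config.filter_threshold,
            use_absorbance=config.use_absorbance,
            smoothing_window=None if config.smoothing is None
            else config.smoothing.window,
            smoothing_polyorder=2 if config.smoothing is None
            else config.smoothing.polyorder,
            range_lo=lo, range_hi=hi,
            normalize_at_nm=config.normalize_at_nm,
            deriv_window=None if config.derivative is None
            else config.derivative.window,
            deriv_polyorder=2 if config.derivative is None
            else config.derivative.polyorder,
            deriv_order=1 if config.derivative is None
            else config.derivative.deriv)

    def _validate_params(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be 1-d and strictly increasing")
        if self.smoothing_window is not None:
            SGConfig(self.smoothing_window, self.smoothing_polyorder, 0).validate()
        if self.deriv_window is not None:
            SGConfig(self.deriv_window, self.deriv_polyorder,
                     self.deriv_order).validate()
        if (self.range_lo is None) != (self.range_hi is None):
            raise ValueError("range_lo and range_hi must be set together")
        if self.range_lo is not None and self.range_lo >= self.range_hi:
            raise ValueError("range_lo must be < range_hi")

    def fit(self, X, y=None):
        self._validate_params()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(np.asarray(self.wavelengths)):
            raise ValueError("X columns must match the wavelength grid")
        if self.use_filter:
            if X.shape[0] < 3:
                raise ValueError("outlier filter needs at least 3 spectra")
            self.reference_median_ = np.median(X, axis=0)
        else:
            self.reference_median_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def outlier_mask(self, X) -> np.ndarray:
        """Boolean outlier flags for the rows of ``X`` (reflectance)."""
        if not self.use_filter:
            return np.zeros(np.atleast_2d(X).shape[0], dtype=bool)
        _, out_idx = spectrum_outlier_filter(
            X, self.filter_threshold, reference_median=self.reference_median_)
        mask = np.zeros(np.atleast_2d(X).shape[0], dtype=bool)
        mask[out_idx] = True
        return mask

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_in_"):
            raise RuntimeError("SpectralPreprocessor is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        wl = np.asarray(self.wavelengths, dtype=float)
        if X.shape[1] != wl.size:
            raise ValueError("X columns must match the wavelength grid")
        out = X.copy()
        # (2) reflectance -> absorbance; non-positive values are clipped to
        # the smallest positive value of the row before the log (matrix-level
        # analogue of the per-pixel masking in spectra.to_absorbance).
        if self.use_absorbance:
            floor = np.finfo(float).tiny
            out = -np.log(np.maximum(out, floor)) / np.log(ABSORBANCE_LOG_BASE)
        # (3) smoothing
        spacing = float(np.mean(np.diff(wl)))
        if self.smoothing_window is not None:
            out = savitzky_golay(out, self.smoothing_window,
                                 self.smoothing_polyorder, 0, spacing)
        # (4) wavelength-range selection
        if self.range_lo is not None:
            sel = (wl >= self.range_lo) & (wl <= self.range_hi)
            if not sel.any():
                raise ValueError(
                    f"range [{self.range_lo}, {self.range_hi}] nm selects no "
                    "pixels")
            out = out[:, sel]
            wl = wl[sel]
            spacing = float(np.mean(np.diff(wl))) if wl.size > 1 else spacing
        # (5) normalisation to zero at a wavelength
        if self.normalize_at_nm is not None:
            lam = float(self.normalize_at_nm)
            if not (wl[0] <= lam <= wl[-1]):
                raise ValueError(
                    f"normalisation wavelength {lam} nm outside the selected "
                    f"range [{wl[0]}, {wl[-1]}] nm")
            ref = np.array([np.interp(lam, wl, row) for row in out])
            out = out - ref[:, None]
        # (6) derivative
        if self.deriv_window is not None:
            out = savitzky_golay(out, self.deriv_window, self.deriv_polyorder,
                                 self.deriv_order, spacing)
        self.output_wavelengths_ = wl
        return out


def apply_pipeline(dataset: SpectraDataset, config: PreprocessConfig
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the full fixed-order pipeline to a reflectance dataset.

    Returns ``(features, kept_indices)``: one feature row per kept spectrum,
    columns the pixels of the selected range.  Config invariants are checked
    before any computation; the outlier filter (step 1) uses the whole
    dataset, matching the out-of-cross-validation use.
    """
    config.validate()
    if dataset.kind != REFLECTANCE:
        raise SpectrumError("apply_pipeline expects a reflectance dataset")
    pre = SpectralPreprocessor.from_config(dataset.grid.wavelengths, config)
    pre.fit(dataset.values)
    mask = pre.outlier_mask(dataset.values)
    kept = np.flatnonzero(~mask)
    if kept.size == 0:
        raise SpectrumError("outlier filter removed every spectrum")
    features = pre.transform(dataset.values[kept])
    return features, kept
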