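"""Synthetic grape-like spectra with known ground truth.

Real white-grape absorbance spectra show chlorophyll bands near 450 and
660 nm (which fade during storage), water O-H bands near 760, 969 and
1450 nm, and sugar-linked C-H/O-H absorbance around 1200 nm that grows with
the soluble-solids content (%Brix).  The generator models absorbance as a
baseline plus Gaussian bands whose amplitudes are linear in Brix and storage
day, converts it to a true reflectance profile ``R = 10**(-A)``, perturbs it
with per-sample multiplicative/additive scatter and per-pixel profile noise,
and then pushes every sample through the full mock-instrument measurement
procedure, so the generated dataset carries realistic detector effects and a
complete ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .instrument import (
    DEFAULT_N_AVERAGES,
    DEFAULT_TYPICAL_IT_MS,
    MockSpectrometerSpec,
    SampleOpticalModel,
    measure_sample,
    perform_calibration,
)
from .spectra import REFLECTANCE, SpectraDataset

#: Flat true reflectance of the semi-transparent Teflon white reference.
#: The reference standard defines the reflectance scale of the measurement
#: (every calibrated value is a ratio against it), so its own profile is
#: unity in the simulator's reflectance units.
TEFLON_REFLECTANCE = 1.0


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorbance band.

    ``amplitude = base_amplitude + brix_coefficient * brix
    + day_coefficient * day`` multiplies ``exp(-(lam-center)^2 / (2 width^2))``.
    Units: nm for center/width, absorbance units (AU) for amplitudes,
    AU / %Brix and AU / day for the coefficients.
    """

    center: float
    width: float
    base_amplitude: float
    brix_coefficient: float = 0.0
    day_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")


def default_bands() -> tuple[BandModel, ...]:
    """Grape-like default band set (chlorophyll / water / sugar)."""
    return (
        BandModel(450.0, 18.0, 0.45, 0.0, -0.012),   # chlorophyll, fades
        BandModel(660.0, 14.0, 0.35, 0.0, -0.015),   # chlorophyll, fades
        BandModel(760.0, 20.0, 0.15, 0.0, 0.0),      # water O-H 3rd overtone
        # water O-H 2nd overtone; dissolved sugar reshapes this band, which
        # is what makes Brix visible to a silicon (VIS-range) detector
        BandModel(969.0, 28.0, 0.30, 0.010, 0.0),
        BandModel(1200.0, 30.0, 0.15, 0.012, 0.0),   # sugar C-H, grows w/ Brix
        BandModel(1450.0, 45.0, 0.55, 0.0, 0.0),     # water O-H 1st overtone
    )


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic dataset.

    Defaults follow a grocery-store white-grape storage study: Brix uniform
    over the observed 6.6-25.1 %Brix span, storage-day classes
    {1, 3, 5, 6, 8, 10}, mild multiplicative/additive scatter and 0.01 AU
    per-pixel profile noise.

    ``day_scale`` controls how the day label enters the band amplitudes:
    ``"value"`` uses the day number itself, ``"index"`` the class index
    0..n_classes-1 (useful when calibrating class separation).
    ``brix_tilt`` adds a broad linear baseline tilt proportional to Brix
    (AU per 1000 nm per %Brix).  ``scatter_baseline_sd`` adds a per-sample
    smooth random baseline (Gaussian process with squared-exponential kernel,
    length scale ``scatter_baseline_length_nm``) — the wavelength-dependent
    scatter variation that derivative preprocessing exists to remove: the
    compositional signal then survives only in the local band slopes.
    """

    bands: tuple[BandModel, ...] = field(default_factory=default_bands)
    baseline: float = 0.25
    brix_range: tuple[float, float] = (6.6, 25.1)
    day_classes: tuple[int, ...] = (1, 3, 5, 6, 8, 10)
    day_scale: str = "value"
    brix_tilt: float = 0.0
    tilt_ref_nm: float = 700.0
    scatter_multiplicative_sd: float = 0.02
    scatter_additive_sd: float = 0.01
    scatter_baseline_sd: float = 0.0
    scatter_baseline_length_nm: float = 60.0
    noise_sd: float = 0.01
    n_samples: int = 100

    def validate(self) -> None:
        if not self.bands:
            raise ValueError("need at least one band")
        if not (0 < self.brix_range[0] < self.brix_range[1]):
            raise ValueError("brix range must be positive and increasing")
        for sd in (self.scatter_multiplicative_sd, self.scatter_additive_sd,
                   self.scatter_baseline_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("noise/scatter sds must be >= 0")
        if self.day_scale not in ("value", "index"):
            raise ValueError("day_scale must be 'value' or 'index'")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def true_absorbance(brix: float, day: float, lam, config: GeneratorConfig
                    ) -> np.ndarray:
    """Noise-free absorbance of a sample at wavelengths ``lam`` (nm).

    ``day`` is the value on the configured day scale (day number or class
    index).  Clipped below at a small positive value so the implied
    reflectance stays in (0, 1].
    """
    lam = np.asarray(lam, dtype=float)
    A = np.full_like(lam, config.baseline, dtype=float)
    A += config.brix_tilt * brix * (lam - config.tilt_ref_nm) / 1000.0
    for b in config.bands:
        amp = (b.base_amplitude + b.brix_coefficient * brix
               + b.day_coefficient * day)
        A += amp * np.exp(-((lam - b.center) ** 2) / (2.0 * b.width ** 2))
    return np.maximum(A, 1e-4)


def _baseline_cholesky(config: GeneratorConfig, grid_wl: np.ndarray
                       ) -> np.ndarray | None:
    """Cholesky factor of the smooth-baseline GP covariance on a grid."""
    if config.scatter_baseline_sd <= 0:
        return None
    d = (grid_wl[:, None] - grid_wl[None, :]) / config.scatter_baseline_length_nm
    K = config.scatter_baseline_sd ** 2 * np.exp(-0.5 * d ** 2)
    return np.linalg.cholesky(K + 1e-10 * np.eye(grid_wl.size))


def _sample_optical_model(brix: float, day_val: float, day_label,
                          config: GeneratorConfig, grid_wl: np.ndarray,
                          rng: np.random.Generator,
                          baseline_chol: np.ndarray | None = None
                          ) -> SampleOpticalModel:
    """Optical profile on one instrument grid, with scatter and profile noise."""
    m = 1.0 + rng.normal() * config.scatter_multiplicative_sd
    o = rng.normal() * config.scatter_additive_sd
    eps = rng.normal(size=grid_wl.size) * config.noise_sd
    A_obs = (m * true_absorbance(brix, day_val, grid_wl, config) + o + eps)
    if baseline_chol is not None:
        A_obs = A_obs + baseline_chol @ rng.normal(size=grid_wl.size)
    A_obs = np.maximum(A_obs, 1e-4)

    def reflectance(lam, _wl=grid_wl, _A=A_obs):
        return np.power(10.0, -np.interp(np.asarray(lam, float), _wl, _A))

    return SampleOpticalModel(reflectance,
                              descriptor={"brix": brix, "day": day_label,
                                          "mult": m, "offset": o})


def teflon_sample() -> SampleOpticalModel:
    """Semi-transparent Teflon reference block (flat, bright reflectance)."""
    return SampleOpticalModel(
        lambda lam: np.full(np.asarray(lam, float).shape, TEFLON_REFLECTANCE),
        descriptor={"material": "teflon"})


@dataclass
class SyntheticDataset:
    """Generated spectra per spectrometer plus full ground truth."""

    datasets: dict[str, SpectraDataset]
    brix: np.ndarray
    day: np.ndarray
    truth: dict
    config: GeneratorConfig

    def __getitem__(self, name: str) -> SpectraDataset:
        return self.datasets[name]


def generate_dataset(config: GeneratorConfig,
                     spectrometers: dict[str, MockSpectrometerSpec] | None = None,
                     seed: int = 0,
                     typical_it: float = DEFAULT_TYPICAL_IT_MS,
                     n_avg: int = DEFAULT_N_AVERAGES) -> SyntheticDataset:
    """Generate a labelled dataset through the full measurement procedure.

    Brix values are drawn uniformly over the configured range; day classes
    are assigned in (shuffled) balanced rotation.  Each spectrometer is
    calibrated once against the Teflon reference, then every sample is
    measured with the probe/optimise/acquire procedure.  Fully reproducible
    under ``seed``; the per-sample ground truth (true band amplitudes,
    scatter draws) is retained.
    """
    config.validate()
    if spectrometers is None:
        spectrometers = {"vis": MockSpectrometerSpec.default_vis(),
                         "nir": MockSpectrometerSpec.default_nir()}
    rng = np.random.default_rng(seed)
    n = config.n_samples
    brix = rng.uniform(*config.brix_range, size=n)
    day_labels = np.asarray(config.day_classes)[
        rng.permutation(np.arange(n) % len(config.day_classes))]
    day_index = {d: i for i, d in enumerate(config.day_classes)}
    day_vals = (np.array([day_index[d] for d in day_labels], dtype=float)
                if config.day_scale == "index"
                else day_labels.astype(float))

    sugar_bands = [b for b in config.bands if b.brix_coefficient != 0]
    truth = {
        "band_amplitude_1200": (
            None if not sugar_bands else
            sugar_bands[0].base_amplitude
            + sugar_bands[0].brix_coefficient * brix),
        "mult": np.empty(n), "offset": np.empty(n),
    }

    datasets: dict[str, SpectraDataset] = {}
    calib_rng = np.random.default_rng(rng.integers(2 ** 31))
    sample_seeds = rng.integers(2 ** 31, size=(len(spectrometers), n))
    for j, (name, spec) in enumerate(spectrometers.items()):
        calib = perform_calibration(spec, teflon_sample(), it=typical_it,
                                    n_avg=n_avg, seed=calib_rng)
        scatter_rng = np.random.default_rng(sample_seeds[j, 0] ^ 0x5EED)
        chol = _baseline_cholesky(config, spec.grid.wavelengths)
        rows = []
        for i in range(n):
            model = _sample_optical_model(brix[i], day_vals[i], day_labels[i],
                                          config, spec.grid.wavelengths,
                                          scatter_rng, chol)
            if j == 0:
                truth["mult"][i] = model.descriptor["mult"]
                truth["offset"][i] = model.descriptor["offset"]
            try:
                rec = measure_sample(spec, model, calib, typical_it=typical_it,
                                     n_avg=n_avg, seed=int(sample_seeds[j, i]),
                                     sample_id=f"s{i:04d}")
            except Exception as exc:
                raise RuntimeError(f"sample {i} ({name}): {exc}") from exc
            rows.append(rec.reflectance.values)
        datasets[name] = SpectraDataset(
            spec.grid, np.vstack(rows), REFLECTANCE,
            [f"s{i:04d}" for i in range(n)], brix=brix.copy(),
            day=day_labels.copy(), meta={"device_id": name, "seed": int(seed)})
    return SyntheticDataset(datasets, brix, day_labels, truth, config)


def make_day_classification_dataset(separation: float,
                                    n_per_class: int = 12,
                                    seed: int = 0,
                                    spectrometer: MockSpectrometerSpec | None = None,
                                    ) -> SyntheticDataset:
    """Dataset whose storage-day classes sit at a controlled separation.

    ``separation`` is defined per pixel at the day band's peak: adjacent
    class means of measured absorbance at the 660 nm chlorophyll pixel differ
    by ``separation`` times the within-class absorbance sd at that pixel.
    The within-class sd is self-calibrated from a pilot batch generated with
    zero day signal under the same seed, so the separation is meaningful
    regardless of the instrument noise settings.  Multiplicative/additive
    scatter is switched off here: it is spatially correlated across pixels,
    which would make the per-pixel separation dial ill-defined; within-class
    variation is then the independent profile and detector noise.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if spectrometer is None:
        spectrometer = MockSpectrometerSpec.default_vis()
    day_band = BandModel(660.0, 10.0, 0.35, 0.0, 0.0)
    base_bands = tuple(b for b in default_bands() if b.center != 660.0)
    pilot_cfg = GeneratorConfig(bands=base_bands + (day_band,),
                                day_scale="index", n_samples=12,
                                scatter_multiplicative_sd=0.0,
                                scatter_additive_sd=0.0)
    pilot = generate_dataset(pilot_cfg, {"cal": spectrometer}, seed=seed)
    wl = spectrometer.grid.wavelengths
    px = int(np.argmin(np.abs(wl - 660.0)))
    a_pilot = -np.log10(np.clip(pilot["cal"].values[:, px], 1e-12, None))
    sigma_w = float(np.std(a_pilot, ddof=1))

    n_classes = len(pilot_cfg.day_classes)
    cfg = replace(pilot_cfg,
                  bands=base_bands + (replace(day_band,
                                              day_coefficient=separation * sigma_w),),
                  n_samples=n_per_class * n_classes)
    out = generate_dataset(cfg, {spectrometer.device_id: spectrometer},
                           seed=seed + 1)
    out.truth["sigma_within"] = sigma_w
    out.truth["day_step_au"] = separation * sigma_w
    return out
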