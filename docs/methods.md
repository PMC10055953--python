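# Methods

This note records the models behind `visnir`, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
conventions. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectral model and calibration

A spectrum is a vector of per-pixel values on a strictly increasing
wavelength grid (nm), tagged as intensity, reflectance or absorbance, with a
per-pixel validity mask. Reflectance is the dark-corrected ratio against a
semi-transparent Teflon reference measured in the same interactance
geometry:

    R = (I_sample − I_dark) / (I_teflon − I_dark)

The reference standard defines the reflectance scale: a sample optically
identical to the reference reads R = 1. Absorbance is decadic,
`A = log10(1/R)` — the base is not dictated by the ratio definition, and
base 10 is the chemometrics convention; it lives in one constant
(`spectra.ABSORBANCE_LOG_BASE`).

Numerical conventions:

- **Denominator guard.** Pixels whose dark-corrected reference signal falls
  below 1e-9 of the reference dynamic range are masked invalid. Masking
  propagates (one dead pixel never aborts a measurement); an all-masked
  spectrum is an error.
- **Non-positive reflectance** on a valid pixel is masked with a logged
  warning before the log transform.
- **Interpolation** at arbitrary wavelengths is linear between the
  bracketing valid pixels; exact pixel hits return the stored value;
  extrapolation is an error.
- **VIS/NIR merge.** The two channels have different pixel pitches
  (2 nm vs 8.2 nm), so the values at the 918 nm join are interpolated. The
  offset `nir(918) − vis(918)` is subtracted from the whole NIR side; the
  merged grid keeps the native, non-uniform pixel spacing (the downstream
  operators are pixel-index based, and resampling would correlate
  neighbouring noise). Smoothing before merging is the caller's duty.

## Mock spectrometer

Per pixel, the expected detector count for integration time `it` (ms) is

    dark_offset + dark_current·it + lamp_on · responsivity(λ) · R_true(λ) · it

clipped to `[0, saturation_count]`, with Gaussian read noise
(`read_noise_sd`, counts) plus a shot-like term of variance
`shot_noise_scale² · expected_count` — the simplest noise model that makes
1/√n averaging a testable physical property. `responsivity` absorbs the
lamp profile, modelled as a 2850 K blackbody shape peaking in the NIR.
Defaults (VIS channel): grid 445–1061 nm at 2 nm/pixel (309 px),
dark offset 500 counts, dark current 0.5 counts/ms, 16-bit saturation
(65535), read noise 10 counts, peak responsivity 480 counts/(ms·unit), so a
unit-reflectance sample at the 100 ms default integration time sits at
roughly 70 % of saturation. The NIR channel uses 877–1689 nm at
8.2 nm/pixel (100 px) with slightly higher read noise. Two channels are
driven sequentially as two independent instances.

**Measurement procedure.** Probe at the typical integration time
(default 100 ms), saturation check (one retry at a quarter of the time,
then error), integration-time optimisation, final averaged acquisition
(default 10 averages) with a per-measurement dark spectrum.

**Integration-time rescaling.** Reference spectra are recorded at the
calibration integration time; when a sample is measured at a different
time, the dark-corrected reference signal is scaled linearly by the ratio
of integration times before the calibration ratio (the detector is linear
in `it` by construction). This rescaled ratio is the physical,
`it`-invariant reflectance stored in measurement records. The *raw*,
unrescaled ratio grows with `it`; that is the quantity the optimiser
targets: `it_opt = min(0.90 · typical_it / max R, 5000 ms)` puts the raw
ratio of the final acquisition at ≈ 0.90 — just below the reference level,
maximising SNR without saturating. Both conventions are exposed
(`calibrated_reflectance(..., rescale=...)`).

## Preprocessing

Fixed order, each step individually switchable, never reordered:
(1) outlier filter, (2) absorbance, (3) Savitzky–Golay smoothing,
(4) wavelength-range selection, (5) normalisation to zero by subtraction at
a chosen wavelength, (6) Savitzky–Golay derivative. Normalisation before
the derivative means the derivative destroys the zero again; the order is
kept anyway because it is the established pipeline order this toolbox
reproduces.

- **Savitzky–Golay** is a per-point local polynomial least-squares fit
  (scipy's implementation; derivatives scaled per nm by the pixel spacing).
  Edge points are evaluated from the fit polynomial of the first/last full
  window so grids stay aligned across samples. On non-uniform (merged)
  grids the derivative uses the mean local spacing — an approximation,
  documented as such.
- **Outlier filter.** "Atypical spectrum" is operationalised as: Pearson
  correlation with the pointwise-median spectrum below a threshold
  (default 0.9), or any reflectance outside [0, 1.2] (physical bounds with
  headroom for samples slightly brighter than the reference). It is
  deterministic and dataset-relative; inside cross-validation the median is
  learned on training folds only, so no information leaks from test folds.
  Flagged training spectra are dropped from fitting; test spectra are always
  predicted, so pooled CV metrics cover every sample.

## Estimators

**PLSR** is PLS1 NIPALS with X- and y-deflation on mean-centred data and no
unit-variance scaling (all pixels share units); collapsed coefficients
`B = W(PᵀW)⁻¹q` give predictions in one matrix product. If the residual
covariance is exhausted before the requested component count, fitting stops
early with a warning and records the achieved count. At full rank the
predictions coincide with ordinary least squares, which is the test oracle.

**LDA** solves the generalised eigenproblem of between- versus within-class
scatter with the within-scatter regularised as `Sw + ε·trace(Sw)/p · I`
(default ε = 1e-6, needed because spectra typically have more pixels than
samples); classification is by nearest class mean in the discriminant
space, components ordered by eigenvalue with the sign fixed so the
largest-magnitude loading is positive.

**Scores.** R² = 1 − SS_res/SS_tot; RMSE; RPD = sd(y)/RMSE with the
*population* standard deviation of the reference values over the evaluation
set (the σ in the RPD definition is read as the sd of the reference values —
the standard convention); accuracy is the exact-match fraction. Reported
sets: calibration (R2C/RMSEC, refit on all training data),
cross-validation (R2CV/RMSECV or ACCV, pooled out-of-fold predictions),
prediction (R2P/RMSEP on a held-out split). The regression line
(slope/intercept) and bias = mean(ŷ − y) are computed on the CV
predictions, and the RPD uses the CV residuals.

**Cross-validation and selection.** k-fold CV with k = 10 by default (the
common chemometrics choice at n ≈ 80–100), shuffled under a recorded seed;
folds partition the samples exactly once. The hold-out split is random
80:20 (train size ⌈0.8n⌉) under a recorded seed, unstratified by default.
Grid search exhaustively evaluates preprocessing × hyperparameter products,
selecting minimal RMSECV (regression) or maximal ACCV (classification);
ties break to fewer components, then smaller smoothing window, then grid
order; the full per-configuration audit is retained.

## Synthetic data

The generator emulates a storage study of grocery-store white grapes:
absorbance = baseline (0.25 AU) + Gaussian bands. Chlorophyll bands at
450/660 nm fade with storage day (−0.012/−0.015 AU per day); water bands at
760/969/1450 nm; a sugar band at 1200 nm growing by 0.012 AU per %Brix; and
the 969 nm water band reshaped by dissolved sugar (+0.010 AU per %Brix),
which is what makes Brix visible to a silicon (VIS-range) detector. Brix is
drawn uniformly over 6.6–25.1 %Brix (a realistic observed span); day
classes are {1, 3, 5, 6, 8, 10} in balanced rotation. Per sample:
multiplicative scatter (sd 0.02), additive offset (sd 0.01 AU), per-pixel
profile noise (sd 0.01 AU, frozen into the sample's optical profile —
surface inhomogeneity, distinct from the detector noise drawn per readout),
and optionally a smooth random baseline (Gaussian process,
squared-exponential kernel, length scale 60 nm). Every sample is measured
through the full mock-instrument procedure.

The smooth-baseline option exists because with purely linear band
arithmetic a linear model absorbs any low-dimensional additive nuisance;
wavelength-dependent baseline variation is the regime where derivative
preprocessing genuinely earns its place, and with it enabled
(sd 0.10, profile noise 0.002) grid search reproducibly selects a
derivative configuration — the compositional signal survives only in the
local band slopes.

**Calibrated day-classification datasets.** `make_day_classification_dataset`
defines class separation per pixel at the 660 nm day-band peak: adjacent
class means of measured absorbance differ by `separation` × the
within-class sd at that pixel, self-calibrated from a pilot batch with zero
day signal under the same seed. Scatter is switched off there because it is
spatially correlated across pixels, which would make a per-pixel separation
dial ill-defined. The evaluation pipeline for these datasets is absorbance
+ crop to the 620–700 nm chlorophyll window with LDA shrinkage 0.1 (pixel
count below the training-fold size, moderate regularisation) — chosen so
the classifier's error reflects class overlap rather than p ≫ n estimation
noise.

What the generator does **not** emulate: radiative-transfer or
interactance-geometry optics, temperature drift of the InGaAs channel,
biological ripening kinetics, or operator errors (a sample removed
mid-measurement). Passing tests therefore show that the pipeline recovers
the parameters of this band-plus-scatter world through the simulated
instrument; they do not certify performance on real fruit spectra.

## Problem sizes

The regression study uses n = 100 samples on the 309-pixel VIS grid with an
8-configuration preprocessing grid × 15 component counts under 10-fold CV;
the classification study uses 6 × 12 samples per dataset across 20 seeds and
three separations. These sizes give stable metrics (seed-to-seed R2CV
spread ≈ 0.002) while the whole suite runs in well under a minute.

## Known limitations

- The merge keeps native pixel spacing; derivative spacing on merged grids
  is a mean-spacing approximation.
- Wavelength calibration is treated as exact (no drift model); grid ranges
  are data, not constants.
- The outlier filter is one reasonable operationalisation of "atypical
  spectrum"; real instruments may need fruit-specific rules, and outlier
  counts are not comparable across filter definitions.
- PLS is univariate (PLS1); multi-target regression is out of scope.
- Model persistence stores collapsed coefficients only (enough to predict,
  not to resume fitting).
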