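"""File formats and configuration schemas.

Spectra travel as wide CSV (first column ``wavelength_nm``, one column per
sample, header row carrying the sample ids) with a JSON sidecar for the kind
tag, targets and metadata.  Measurement records and fitted models are
versioned JSON payloads validated with pydantic; run configurations are
schema-validated before any computation and reject unknown keys.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .chemometrics import PLSRegressionNIPALS, ShrinkageLDA
from .instrument import MeasurementRecord
from .preprocess import PreprocessConfig
from .spectra import INTENSITY, REFLECTANCE, SpectraDataset, Spectrum, WavelengthGrid

MEASUREMENT_SCHEMA_VERSION = 1
MODEL_SCHEMA_VERSION = 1


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_spectra_csv(dataset: SpectraDataset, path) -> None:
    """Write a dataset as wide CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"wavelength_nm": dataset.grid.wavelengths})
    for i, sid in enumerate(dataset.sample_ids):
        df[sid] = dataset.values[i]
    df.to_csv(path, index=False)
    meta = {"kind": dataset.kind,
            "brix": None if dataset.brix is None else list(map(float, dataset.brix)),
            "day": None if dataset.day is None else [int(d) for d in dataset.day],
            "meta": dataset.meta}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_spectra_csv(path) -> SpectraDataset:
    """Read a wide spectra CSV (and its sidecar, when present).

    Validation errors report the offending CSV line: non-monotone or
    duplicated wavelengths, duplicate sample ids, ragged/missing values.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    if not header or header[0] != "wavelength_nm":
        raise ValueError("first column must be 'wavelength_nm'")
    ids = header[1:]
    if len(set(ids)) != len(ids):
        dupes = {s for s in ids if ids.count(s) > 1}
        raise ValueError(f"duplicate sample ids in header: {sorted(dupes)}")
    # round_trip parsing: wavelengths and values must survive CSV exactly
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = header
    if df.isna().any().any():
        bad = int(np.where(df.isna().any(axis=1))[0][0]) + 2  # 1-based + header
        raise ValueError(f"missing/ragged value at line {bad}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    diffs = np.diff(wl)
    if np.any(diffs <= 0):
        line = int(np.where(diffs <= 0)[0][0]) + 3
        raise ValueError(f"wavelengths not strictly increasing at line {line}")
    sample_ids = ids
    kind, brix, day, meta = REFLECTANCE, None, None, {}
    sc = _sidecar(path)
    if sc.exists():
        m = json.loads(sc.read_text())
        kind = m.get("kind", REFLECTANCE)
        brix = None if m.get("brix") is None else np.asarray(m["brix"], float)
        day = None if m.get("day") is None else np.asarray(m["day"])
        meta = m.get("meta", {})
    values = df[sample_ids].to_numpy(dtype=float).T
    return SpectraDataset(WavelengthGrid(wl), values, kind, sample_ids,
                          brix=brix, day=day, meta=meta)


def read_targets_csv(path) -> pd.DataFrame:
    """Targets CSV with columns sample_id and brix and/or day."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("targets CSV must have a 'sample_id' column")
    if not ({"brix", "day"} & set(df.columns)):
        raise ValueError("targets CSV needs a 'brix' and/or 'day' column")
    return df


def attach_targets(dataset: SpectraDataset, targets: pd.DataFrame
                   ) -> SpectraDataset:
    t = targets.set_index("sample_id")
    missing = [s for s in dataset.sample_ids if s not in t.index]
    if missing:
        raise ValueError(f"targets missing for sample(s) {missing[:5]}")
    if "brix" in t.columns:
        dataset.brix = t.loc[dataset.sample_ids, "brix"].to_numpy(float)
    if "day" in t.columns:
        dataset.day = t.loc[dataset.sample_ids, "day"].to_numpy()
    return dataset


# --------------------------------------------------------------------------
# measurement record JSON
# --------------------------------------------------------------------------

class MeasurementPayload(BaseModel):
    """Versioned JSON schema of one measurement record."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = MEASUREMENT_SCHEMA_VERSION
    sample_id: str
    device_id: str
    it_opt_ms: float = Field(gt=0)
    n_averages: int = Field(ge=1)
    wavelengths_nm: list[float]
    intensity: list[float]
    dark: list[float]
    reflectance: list[float]
    timestamp: str | None = None

    @model_validator(mode="after")
    def _lengths(self):
        n = len(self.wavelengths_nm)
        for name in ("intensity", "dark", "reflectance"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from wavelengths_nm")
        if self.schema_version > MEASUREMENT_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}")
        return self


def write_measurement_json(record: MeasurementRecord, path) -> None:
    payload = MeasurementPayload(
        sample_id=record.sample_id, device_id=record.device_id,
        it_opt_ms=record.it_opt_ms, n_averages=record.n_averages,
        wavelengths_nm=list(map(float, record.raw_intensity.wavelengths)),
        intensity=list(map(float, record.raw_intensity.values)),
        dark=list(map(float, record.dark.values)),
        reflectance=list(map(float, record.reflectance.values)),
        timestamp=record.timestamp)
    Path(path).write_text(payload.model_dump_json(indent=1))


def read_measurement_json(path) -> MeasurementRecord:
    payload = MeasurementPayload.model_validate_json(Path(path).read_text())
    grid = WavelengthGrid(np.asarray(payload.wavelengths_nm))
    meta = {"integration_time_ms": payload.it_opt_ms,
            "n_averages": payload.n_averages, "device_id": payload.device_id}
    return MeasurementRecord(
        sample_id=payload.sample_id, device_id=payload.device_id,
        it_opt_ms=payload.it_opt_ms, n_averages=payload.n_averages,
        raw_intensity=Spectrum(grid, payload.intensity, INTENSITY, meta=dict(meta)),
        dark=Spectrum(grid, payload.dark, INTENSITY,
                      meta={**meta, "lamp_on": False}),
        reflectance=Spectrum(grid, payload.reflectance, REFLECTANCE,
                             meta=dict(meta)),
        timestamp=payload.timestamp)


# --------------------------------------------------------------------------
# fitted-model JSON (coefficients only)
# --------------------------------------------------------------------------

def model_to_json(config: PreprocessConfig, estimator, wavelengths, path) -> None:
    doc: dict = {"schema_version": MODEL_SCHEMA_VERSION,
                 "preprocess": config.to_dict(),
                 "wavelengths_nm": list(map(float, wavelengths))}
    if isinstance(estimator, PLSRegressionNIPALS):
        doc["estimator"] = {
            "type": "plsr", "n_components": estimator.n_components_,
            "x_mean": estimator.x_mean_.tolist(),
            "y_mean": estimator.y_mean_,
            "coef": estimator.coef_.tolist()}
    elif isinstance(estimator, ShrinkageLDA):
        doc["estimator"] = {
            "type": "lda", "n_components": estimator.n_components_,
            "xbar": estimator.xbar_.tolist(),
            "scalings": estimator.scalings_.tolist(),
            "class_centers": estimator.class_centers_.tolist(),
            "classes": np.asarray(estimator.classes_).tolist()}
    else:
        raise TypeError(f"cannot serialise {type(estimator).__name__}")
    Path(path).write_text(json.dumps(doc, indent=1))


def model_from_json(path) -> tuple[PreprocessConfig, object, np.ndarray]:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version", 0) > MODEL_SCHEMA_VERSION:
        raise ValueError("unsupported model schema version")
    config = PreprocessConfig.from_dict(doc["preprocess"])
    wl = np.asarray(doc["wavelengths_nm"], float)
    e = doc["estimator"]
    if e["type"] == "plsr":
        est = PLSRegressionNIPALS(n_components=e["n_components"])
        est.x_mean_ = np.asarray(e["x_mean"], float)
        est.y_mean_ = float(e["y_mean"])
        est.coef_ = np.asarray(e["coef"], float)
        est.n_components_ = e["n_components"]
        est.n_features_in_ = est.x_mean_.size
    elif e["type"] == "lda":
        est = ShrinkageLDA(n_components=e["n_components"])
        est.xbar_ = np.asarray(e["xbar"], float)
        est.scalings_ = np.asarray(e["scalings"], float)
        est.class_centers_ = np.asarray(e["class_centers"], float)
        est.classes_ = np.asarray(e["classes"])
        est.n_components_ = e["n_components"]
        est.n_features_in_ = est.xbar_.size
    else:
        raise ValueError(f"unknown estimator type {e['type']!r}")
    return config, est, wl


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

class InstrumentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_averages: int = Field(default=10, ge=1)
    typical_integration_time_ms: float = Field(default=100.0, gt=0)
    spectrometers: Literal["vis", "nir", "both"] = "vis"


class GeneratorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = Field(default=100, ge=1)
    brix_range: tuple[float, float] = (6.6, 25.1)
    day_classes: list[int] = [1, 3, 5, 6, 8, 10]
    noise_sd: float = Field(default=0.01, ge=0)
    scatter_multiplicative_sd: float = Field(default=0.02, ge=0)
    scatter_additive_sd: float = Field(default=0.01, ge=0)
    brix_tilt: float = 0.0


class CVSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int = Field(default=10, ge=2)
    shuffle: bool = True
    seed: int = 0


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    task: Literal["regression", "classification"] = "regression"
    instrument: InstrumentConfig = InstrumentConfig()
    generator: GeneratorSettings = GeneratorSettings()
    preprocess_grid: list[dict] = [{}]
    model_grid: list[dict] = [{"n_components": 5}]
    cv: CVSettings = CVSettings()
    validation_ratio: float = Field(default=0.8, gt=0, lt=1)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json().encode()).hexdigest()[:12]
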