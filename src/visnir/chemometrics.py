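"""Chemometric estimators, quality metrics, cross-validation and grid search.

The regression workhorse is PLS1 partial least squares fitted by NIPALS with
X- and y-deflation on mean-centred data (no unit-variance scaling: all pixels
share units).  Classification uses Fisher linear discriminant analysis from
the generalised eigenproblem of between- versus within-class scatter, the
within-class scatter regularised by a small shrinkage term because spectra
typically have more pixels than samples.

Model quality is reported with the standard chemometric scores: R2 and RMSE
on the calibration set (R2C/RMSEC), under k-fold cross-validation
(R2CV/RMSECV), and on a held-out validation set (R2P/RMSEP); the RPD (ratio
of the reference standard deviation to the RMSE, > 3 conventionally read as
acceptable predictive power); and the cross-validated accuracy ACCV for
classification.  Model selection is a brute-force grid search over
preprocessing configurations and estimator hyperparameters that minimises
RMSECV (regression) or maximises ACCV (classification).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone

from .preprocess import PreprocessConfig, SpectralPreprocessor
from .spectra import SpectraDataset

__all__ = [
    "PLSRegressionNIPALS", "ShrinkageLDA", "CVConfig", "ModelResult",
    "fit_plsr", "predict_plsr", "fit_lda", "score_r2", "score_rmse",
    "score_rpd", "score_accuracy", "kfold_cv", "cross_validate_config",
    "grid_search", "train_val_split", "fit_report",
]


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

class PLSRegressionNIPALS(RegressorMixin, BaseEstimator):
    """PLS1 regression fitted by the NIPALS algorithm.

    Mean-centres ``X`` and ``y`` (no variance scaling) and extracts
    ``n_components`` latent components by successive deflation; the collapsed
    regression coefficients give ``y_hat = (X - x_mean_) @ coef_ + y_mean_``.

    Attributes (after ``fit``): ``x_mean_``, ``y_mean_``, ``x_weights_``,
    ``x_loadings_``, ``y_loadings_``, ``coef_`` and ``n_components_`` (the
    achieved component count, which can fall short of the request when the
    residual has no remaining covariance with ``y``).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have different numbers of samples")
        if n < 2:
            raise ValueError("PLSR needs at least 2 samples")
        max_comp = min(n - 1, p)
        if not (1 <= self.n_components <= max_comp):
            raise ValueError(
                f"n_components must be in [1, {max_comp}] "
                f"(got {self.n_components})")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xd = X - self.x_mean_
        yd = y - self.y_mean_
        if not np.any(np.abs(Xd) > 0):
            raise ValueError("X has zero variance everywhere")
        W, P, Q = [], [], []
        tol = None
        for _ in range(self.n_components):
            w = Xd.T @ yd
            nw = float(np.linalg.norm(w))
            if tol is None:
                tol = max(nw, 1.0) * 1e-12
            if nw <= tol:
                warnings.warn(
                    "NIPALS stopped early: residual covariance exhausted "
                    f"after {len(W)} component(s)", stacklevel=2)
                break
            w /= nw
            t = Xd @ w
            tt = float(t @ t)
            if tt <= np.finfo(float).tiny:
                break
            p_vec = Xd.T @ t / tt
            q = float(yd @ t / tt)
            Xd = Xd - np.outer(t, p_vec)
            yd = yd - q * t
            W.append(w)
            P.append(p_vec)
            Q.append(q)
        if not W:
            raise ValueError("no usable PLS component: X'y is numerically zero")
        self.x_weights_ = np.column_stack(W)
        self.x_loadings_ = np.column_stack(P)
        self.y_loadings_ = np.asarray(Q)
        self.n_components_ = len(W)
        # collapsed coefficients: B = W (P' W)^{-1} q
        self.coef_ = self.x_weights_ @ np.linalg.solve(
            self.x_loadings_.T @ self.x_weights_, self.y_loadings_)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was trained on "
                f"{self.n_features_in_}")
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_


class ShrinkageLDA(ClassifierMixin, BaseEstimator):
    """Fisher linear discriminant analysis with within-scatter shrinkage.

    Solves the generalised eigenproblem of the between-class versus the
    (regularised) within-class scatter; samples are classified by the nearest
    class mean in the discriminant space.  ``n_components`` defaults to
    ``n_classes - 1`` (its upper bound).  The within-class scatter is
    regularised as ``Sw + shrinkage * trace(Sw)/p * I`` so the solver remains
    well-posed when pixels outnumber samples.

    Eigenvectors are ordered by decreasing eigenvalue; each direction's sign
    is fixed so its largest-magnitude loading is positive.
    """

    def __init__(self, n_components: int | None = None, shrinkage: float = 1e-6):
        self.n_components = n_components
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        n, p = X.shape
        if y.shape[0] != n:
            raise ValueError("X and y have different numbers of samples")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("LDA needs at least 2 classes")
        if np.any(counts < 2):
            bad = classes[counts < 2]
            raise ValueError(f"every class needs >= 2 samples; got 1 for {bad}")
        max_comp = classes.size - 1
        ncomp = max_comp if self.n_components is None else int(self.n_components)
        if not (1 <= ncomp <= max_comp):
            raise ValueError(
                f"n_components must be in [1, {max_comp}] (got {ncomp})")
        grand = X.mean(axis=0)
        Sw = np.zeros((p, p))
        Sb = np.zeros((p, p))
        means = np.empty((classes.size, p))
        for k, c in enumerate(classes):
            Xk = X[y == c]
            means[k] = Xk.mean(axis=0)
            D = Xk - means[k]
            Sw += D.T @ D
            d = (means[k] - grand)[:, None]
            Sb += Xk.shape[0] * (d @ d.T)
        reg = self.shrinkage * np.trace(Sw) / p
        if reg <= 0:
            reg = self.shrinkage * max(np.trace(Sb) / p, 1.0)
        Sw_reg = Sw + reg * np.eye(p)
        eigvals, eigvecs = eigh(Sb, Sw_reg)
        order = np.argsort(eigvals)[::-1][:ncomp]
        vecs = eigvecs[:, order]
        for j in range(vecs.shape[1]):
            if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
                vecs[:, j] = -vecs[:, j]
        self.classes_ = classes
        self.means_ = means
        self.xbar_ = grand
        self.scalings_ = vecs
        self.eigenvalues_ = eigvals[order]
        self.n_components_ = ncomp
        self.class_centers_ = (means - grand) @ vecs
        self.n_features_in_ = p
        return self

    def transform(self, X):
        if not hasattr(self, "scalings_"):
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.xbar_) @ self.scalings_

    def predict(self, X):
        Z = self.transform(X)
        d2 = ((Z[:, None, :] - self.class_centers_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


# thin functional wrappers over the estimator classes ----------------------

def fit_plsr(X, y, n_components: int) -> PLSRegressionNIPALS:
    return PLSRegressionNIPALS(n_components=n_components).fit(X, y)


def predict_plsr(model: PLSRegressionNIPALS, X) -> np.ndarray:
    return model.predict(X)


def fit_lda(X, labels, n_components: int | None = None,
            shrinkage: float = 1e-6) -> ShrinkageLDA:
    return ShrinkageLDA(n_components=n_components, shrinkage=shrinkage).fit(
        X, labels)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def _check_pair(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0 or y.size != y_hat.size:
        raise ValueError("y and y_hat must have equal, nonzero lengths")
    return y, y_hat


def score_r2(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y, y_hat = _check_pair(y, y_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined: reference values have zero variance")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def score_rmse(y, y_hat) -> float:
    """Root mean squared error, in the units of ``y``."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def score_rpd(y, y_hat) -> float:
    """Ratio of the reference standard deviation (population) to the RMSE."""
    y, y_hat = _check_pair(y, y_hat)
    rmse = score_rmse(y, y_hat)
    if rmse == 0:
        raise ValueError("RPD undefined: RMSE is zero")
    return float(np.std(y)) / rmse


def score_accuracy(c, c_hat) -> float:
    """Fraction of exact label matches."""
    c = np.asarray(c).ravel()
    c_hat = np.asarray(c_hat).ravel()
    if c.size == 0 or c.size != c_hat.size:
        raise ValueError("labels must have equal, nonzero lengths")
    return float(np.mean(c == c_hat))


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class CVConfig:
    """k-fold cross-validation settings."""

    k: int = 10
    shuffle: bool = True
    seed: int = 0

    def folds(self, n: int) -> list[tuple[np.ndarray, np.ndarray]]:
        if not (2 <= self.k <= n):
            raise ValueError(f"k must be in [2, {n}] (got {self.k})")
        idx = np.arange(n)
        if self.shuffle:
            idx = np.random.default_rng(self.seed).permutation(n)
        parts = np.array_split(idx, self.k)
        return [(np.setdiff1d(idx, test, assume_unique=True), test)
                for test in parts]


@dataclass
class CVResult:
    predictions: np.ndarray       # out-of-fold predictions, original order
    r2cv: float | None = None
    rmsecv: float | None = None
    accv: float | None = None


def kfold_cv(X, y, estimator, cv: CVConfig, task: str = "regression"
             ) -> CVResult:
    """k-fold cross-validation of a fitted-from-scratch estimator per fold.

    Folds partition the samples exactly once; metrics are computed on the
    pooled out-of-fold predictions.  ``estimator`` is cloned per fold.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n = X.shape[0]
    oof = np.empty(n, dtype=float if task == "regression" else y.dtype)
    for i, (train, test) in enumerate(cv.folds(n)):
        est = clone(estimator)
        if task == "classification":
            present, counts = np.unique(y[train], return_counts=True)
            missing = np.setdiff1d(np.unique(y), present)
            if missing.size or np.any(counts < 2):
                raise ValueError(
                    f"fold {i}: training part lost class(es) "
                    f"{list(missing) if missing.size else list(present[counts < 2])}"
                    " (or left a singleton); use fewer folds or more data")
        est.fit(X[train], y[train])
        oof[test] = est.predict(X[test])
    if task == "regression":
        return CVResult(oof, r2cv=score_r2(y, oof), rmsecv=score_rmse(y, oof))
    return CVResult(oof, accv=score_accuracy(y, oof))


def _targets(dataset: SpectraDataset, task: str) -> np.ndarray:
    if task == "regression":
        if dataset.brix is None:
            raise ValueError("dataset has no Brix targets")
        return np.asarray(dataset.brix, dtype=float)
    if dataset.day is None:
        raise ValueError("dataset has no day labels")
    return np.asarray(dataset.day)


def cross_validate_config(dataset: SpectraDataset, config: PreprocessConfig,
                          estimator, cv: CVConfig, task: str = "regression"
                          ) -> CVResult:
    """Leakage-free CV of (preprocessing config, estimator) on a dataset.

    Per fold, the outlier filter's reference median is learned on the
    training part only; flagged training spectra are dropped from fitting
    while every test spectrum receives a prediction, so the pooled
    out-of-fold metrics cover all samples.
    """
    config.validate()
    y = _targets(dataset, task)
    n = dataset.n_samples
    oof = np.empty(n, dtype=float if task == "regression" else y.dtype)
    for i, (train, test) in enumerate(cv.folds(n)):
        pre = SpectralPreprocessor.from_config(dataset.grid.wavelengths, config)
        pre.fit(dataset.values[train])
        keep = train[~pre.outlier_mask(dataset.values[train])]
        if keep.size < 2:
            raise ValueError(f"fold {i}: outlier filter left <2 training spectra")
        est = clone(estimator)
        if task == "classification":
            present, counts = np.unique(y[keep], return_counts=True)
            missing = np.setdiff1d(np.unique(y), present)
            if missing.size or np.any(counts < 2):
                raise ValueError(
                    f"fold {i}: training part lost class(es) or left a "
                    "singleton; use fewer folds or more data")
        est.fit(pre.transform(dataset.values[keep]), y[keep])
        oof[test] = est.predict(pre.transform(dataset.values[test]))
    if task == "regression":
        return CVResult(oof, r2cv=score_r2(y, oof), rmsecv=score_rmse(y, oof))
    return CVResult(oof, accv=score_accuracy(y, oof))


# --------------------------------------------------------------------------
# split, report, grid search
# --------------------------------------------------------------------------

def train_val_split(dataset: SpectraDataset, ratio: float = 0.8, seed: int = 0
                    ) -> tuple[SpectraDataset, SpectraDataset]:
    """Random disjoint, exhaustive split; train size ``ceil(ratio * n)``."""
    n = dataset.n_samples
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.ceil(ratio * n))
    return dataset.subset(np.sort(perm[:n_train])), dataset.subset(
        np.sort(perm[n_train:]))


@dataclass
class ModelResult:
    """All reported scores of one (config, hyperparameters) model."""

    config: dict
    hyperparameters: dict
    n_components: int | None = None
    r2c: float | None = None
    rmsec: float | None = None
    r2cv: float | None = None
    rmsecv: float | None = None
    r2p: float | None = None
    rmsep: float | None = None
    rpd: float | None = None
    accv: float | None = None
    acc_val: float | None = None
    slope: float | None = None
    intercept: float | None = None
    bias: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _make_estimator(task: str, params: dict):
    if task == "regression":
        return PLSRegressionNIPALS(**params)
    if task == "classification":
        return ShrinkageLDA(**params)
    raise ValueError(f"unknown task {task!r}")


def fit_report(train: SpectraDataset, val: SpectraDataset | None,
               config: PreprocessConfig, hyperparameters: dict,
               cv: CVConfig, task: str = "regression") -> ModelResult:
    """Fit one model and fill the full score report.

    Calibration scores (R2C/RMSEC) come from refitting on the whole training
    set; R2CV/RMSECV (or ACCV) from k-fold CV on the training set; R2P/RMSEP
    from the held-out validation set.  The RPD uses the CV residuals; slope
    and intercept are the least-squares line of the CV-estimated versus
    measured values, and bias is their mean difference.
    """
    config.validate()
    y_train = _targets(train, task)
    pre = SpectralPreprocessor.from_config(train.grid.wavelengths, config)
    pre.fit(train.values)
    keep = np.flatnonzero(~pre.outlier_mask(train.values))
    est = _make_estimator(task, hyperparameters)
    est.fit(pre.transform(train.values[keep]), y_train[keep])
    cv_res = cross_validate_config(train, config, est, cv, task)
    result = ModelResult(config=config.to_dict(),
                         hyperparameters=dict(hyperparameters),
                         n_components=getattr(est, "n_components_", None))
    if task == "regression":
        y_fit = est.predict(pre.transform(train.values[keep]))
        result.r2c = score_r2(y_train[keep], y_fit)
        result.rmsec = score_rmse(y_train[keep], y_fit)
        result.r2cv = cv_res.r2cv
        result.rmsecv = cv_res.rmsecv
        result.rpd = score_rpd(y_train, cv_res.predictions)
        slope, intercept = np.polyfit(y_train, cv_res.predictions, 1)
        result.slope = float(slope)
        result.intercept = float(intercept)
        result.bias = float(np.mean(cv_res.predictions - y_train))
        if val is not None:
            y_val = _targets(val, task)
            y_val_hat = est.predict(pre.transform(val.values))
            result.r2p = score_r2(y_val, y_val_hat)
            result.rmsep = score_rmse(y_val, y_val_hat)
    else:
        result.accv = cv_res.accv
        if val is not None:
            y_val = _targets(val, task)
            result.acc_val = score_accuracy(y_val,
                                            est.predict(pre.transform(val.values)))
    return result


@dataclass
class GridSearchResult:
    best_config: PreprocessConfig
    best_params: dict
    best_score: float            # RMSECV (regression) or ACCV (classification)
    best_cv: CVResult
    audit: list = field(default_factory=list)


def grid_search(dataset: SpectraDataset,
                preprocess_grid: Sequence[PreprocessConfig],
                model_grid: Sequence[dict],
                cv: CVConfig,
                task: str = "regression") -> GridSearchResult:
    """Brute-force model selection over the Cartesian product of grids.

    Regression selects the configuration with minimal RMSECV, classification
    the one with ACCV closest to one; ties are broken by fewer components,
    then smaller smoothing window, then grid order.  The full per-config
    audit (or failure cause) is retained.
    """
    if not preprocess_grid or not model_grid:
        raise ValueError("both grids must be nonempty")
    audit: list[dict] = []
    best: tuple | None = None
    order = 0
    for config in preprocess_grid:
        for params in model_grid:
            order += 1
            entry: dict[str, Any] = {"preprocess": config.to_dict(),
                                     "params": dict(params)}
            try:
                est = _make_estimator(task, params)
                res = cross_validate_config(dataset, config, est, cv, task)
            except Exception as exc:  # collected, reported if all fail
                entry["error"] = f"{type(exc).__name__}: {exc}"
                audit.append(entry)
                continue
            if task == "regression":
                score, key_score = res.rmsecv, res.rmsecv
                entry.update(rmsecv=res.rmsecv, r2cv=res.r2cv)
            else:
                score, key_score = res.accv, -res.accv
                entry.update(accv=res.accv)
            audit.append(entry)
            ncomp = params.get("n_components") or 0
            window = (config.smoothing.window if config.smoothing else 0)
            key = (key_score, ncomp, window, order)
            if best is None or key < best[0]:
                best = (key, config, dict(params), score, res)
    if best is None:
        causes = "; ".join(e.get("error", "?") for e in audit[:5])
        raise RuntimeError(f"every grid configuration failed: {causes}")
    _, config, params, score, res = best
    return GridSearchResult(best_config=config, best_params=params,
                            best_score=float(score), best_cv=res, audit=audit)
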