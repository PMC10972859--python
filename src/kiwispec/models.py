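"""Calibration models: full-spectrum PLSR and selected-wavelength MLR.

Both model families predict a physicochemical index from SNV-preprocessed
reflectance:  y_hat = beta_0 + sum_j beta_j * X(lambda_j).  MLR is ordinary
least squares on a small set of selected wavelengths; PLSR compresses the
full band axis into latent variables, with the latent-variable count picked
by k-fold cross-validated RMSE.  SNV is always applied to the *full*
spectrum before any wavelengths are extracted — coefficients are bound to
that convention through the model's preprocessing tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

PREPROCESSING_TAG = "snv-full-spectrum"


class RankDeficiencyError(ValueError):
    """Raised when the MLR design matrix is not of full column rank."""


@dataclass
class CalibratedModel:
    """An intercept plus coefficients bound to named wavelengths."""

    family: str                       # "PLSR" | "MLR"
    intercept: float
    coefficients: np.ndarray          # length m, aligned with wavelengths_nm
    wavelengths_nm: np.ndarray        # length m
    target: str
    units: str = ""
    n_components: int | None = None   # PLSR only
    preprocessing: str = PREPROCESSING_TAG

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.coefficients.shape != self.wavelengths_nm.shape:
            raise ValueError("one coefficient per bound wavelength required")
        if self.family not in ("PLSR", "MLR"):
            raise ValueError("family must be 'PLSR' or 'MLR'")

    @property
    def n_terms(self) -> int:
        return int(self.coefficients.size)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "target": self.target,
            "units": self.units,
            "preprocessing": self.preprocessing,
            "n_components": self.n_components,
            "intercept": self.intercept,
            "terms": [[float(w), float(c)] for w, c in
                      zip(self.wavelengths_nm, self.coefficients)],
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CalibratedModel":
        d = json.loads(text)
        terms = np.asarray(d["terms"], dtype=float).reshape(-1, 2)
        return cls(family=d["family"], intercept=float(d["intercept"]),
                   coefficients=terms[:, 1], wavelengths_nm=terms[:, 0],
                   target=d["target"], units=d.get("units", ""),
                   n_components=d.get("n_components"),
                   preprocessing=d.get("preprocessing", PREPROCESSING_TAG))


def fit_mlr(X: np.ndarray, y: np.ndarray, wavelengths_nm,
            target: str = "", units: str = "") -> CalibratedModel:
    """Ordinary least squares on selected-wavelength SNV values.

    ``X`` is n x m (columns already extracted at ``wavelengths_nm``).
    Rejects under-determined (n <= m + 1) and rank-deficient designs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if n != y.size:
        raise ValueError("X and y disagree on sample count")
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 samples (n={n}, m={m})")
    A = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(A)
    if rank < m + 1:
        # name the offending columns for the user
        _, r = np.linalg.qr(A)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-10 * diag.max()) - 1
        names = [f"{wavelengths_nm[i]:.0f} nm" for i in bad if i >= 0]
        raise RankDeficiencyError(
            "design matrix is rank deficient; collinear wavelengths: "
            + (", ".join(names) or "intercept"))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return CalibratedModel(family="MLR", intercept=float(beta[0]),
                           coefficients=beta[1:],
                           wavelengths_nm=np.asarray(wavelengths_nm, float),
                           target=target, units=units)


def plsr_coefficients(X: np.ndarray, y: np.ndarray,
                      n_components: int) -> tuple[float, np.ndarray]:
    """Intercept and per-band regression vector of a fitted PLSR."""
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y.reshape(-1, 1))
    coef = pls.coef_.ravel()
    intercept = float(pls.intercept_.ravel()[0] - pls._x_mean @ coef)
    return intercept, coef


def _cv_rmse_pls(X: np.ndarray, y: np.ndarray, n_components: int,
                 n_folds: int) -> float:
    kf = KFold(n_splits=n_folds, shuffle=False)
    press = 0.0
    for tr, te in kf.split(X):
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X[tr], y[tr].reshape(-1, 1))
        press += float(np.sum((pls.predict(X[te]).ravel() - y[te]) ** 2))
    return float(np.sqrt(press / len(y)))


def fit_plsr(X: np.ndarray, y: np.ndarray, wavelengths_nm,
             max_lv: int = 15, n_folds: int = 5,
             target: str = "", units: str = "") -> CalibratedModel:
    """Full-spectrum PLSR with the LV count chosen by k-fold RMSECV.

    The model is exported in explicit linear form (intercept plus one
    coefficient per band), which is also the regression vector that
    importance-based wavelength selection consumes.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} samples for "
                         f"{n_folds}-fold cross-validation")
    cap = int(min(max_lv, np.linalg.matrix_rank(X - X.mean(axis=0)),
                  n - int(np.ceil(n / n_folds)) - 1))
    cap = max(cap, 1)
    rmsecv = [_cv_rmse_pls(X, y, lv, n_folds) for lv in range(1, cap + 1)]
    best_lv = 1 + int(np.argmin(rmsecv))
    intercept, coef = plsr_coefficients(X, y, best_lv)
    return CalibratedModel(family="PLSR", intercept=intercept,
                           coefficients=coef,
                           wavelengths_nm=np.asarray(wavelengths_nm, float),
                           target=target, units=units, n_components=best_lv)


def predict(model: CalibratedModel, spectra, grid=None,
            preprocessing: str = PREPROCESSING_TAG,
            tol_nm: float = 1.0) -> np.ndarray:
    """Apply a calibrated model to SNV-preprocessed full-grid spectra.

    ``spectra`` may be a DataFrame whose columns are band centers in nm
    (grid inferred) or an array with an explicit ``grid``.  The model's
    wavelengths are resolved on that grid by nearest neighbor within
    ``tol_nm``; a mismatching preprocessing tag is rejected.
    """
    from .grid import WavelengthGrid

    if preprocessing != model.preprocessing:
        raise ValueError(
            f"preprocessing mismatch: spectra are '{preprocessing}', model "
            f"expects '{model.preprocessing}'")
    if isinstance(spectra, pd.DataFrame):
        grid = WavelengthGrid(spectra.columns.to_numpy(dtype=float))
        X = spectra.to_numpy(dtype=float)
    else:
        if grid is None:
            raise ValueError("an explicit grid is required for array input")
        X = np.asarray(spectra, dtype=float)
    one_dim = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != len(grid):
        raise ValueError("spectra do not lie on the stated grid")
    idx = grid.indices_of(model.wavelengths_nm, tol=tol_nm)
    yhat = model.intercept + X[:, idx] @ model.coefficients
    return yhat[0] if one_dim else yhat
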