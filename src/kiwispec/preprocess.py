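"""Standard normal variate (SNV) scatter correction.

SNV centers and scales each spectrum by its own mean and standard
deviation, removing the multiplicative gain and additive offset that
particle-size and surface-scattering effects impose on diffuse
reflectance measurements.  It is applied per spectrum (rows of a table,
or individual pixels of a hypercube), always on the full band axis.

Convention: the denominator is the population standard deviation
(divide by the number of bands B, not B-1).  Calibrated model
coefficients are scale-sensitive, so this choice is fixed package-wide.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ConstantSpectrumError(ValueError):
    """Raised when a spectrum has zero standard deviation (SNV undefined)."""


def snv(x: np.ndarray) -> np.ndarray:
    """SNV-transform one spectrum: (x - mean(x)) / sd_pop(x).

    The output has mean 0 and population standard deviation 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("snv expects a single 1-D spectrum; see snv_table/snv_cube")
    if x.size < 2:
        raise ValueError("SNV needs at least two bands")
    sd = float(np.std(x))  # population sd: scale-sensitive downstream
    if sd == 0.0 or not np.isfinite(sd):
        raise ConstantSpectrumError(
            "spectrum has zero (or non-finite) standard deviation; SNV undefined"
        )
    return (x - float(np.mean(x))) / sd


def snv_rows(X: np.ndarray) -> np.ndarray:
    """Vectorized SNV over the rows of an N x B matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an N x B matrix")
    sd = X.std(axis=1, keepdims=True)
    bad = ~np.isfinite(sd) | (sd == 0)
    if np.any(bad):
        raise ConstantSpectrumError(
            f"{int(bad.sum())} row(s) have zero standard deviation; SNV undefined"
        )
    return (X - X.mean(axis=1, keepdims=True)) / sd


def snv_table(spectra: pd.DataFrame) -> pd.DataFrame:
    """SNV-transform a spectra table (rows = samples, columns = bands)."""
    out = snv_rows(spectra.to_numpy(dtype=float))
    return pd.DataFrame(out, index=spectra.index, columns=spectra.columns)


def snv_cube(cube, mask: np.ndarray | None = None):
    """Pixel-wise SNV over the masked pixels of a reflectance hypercube.

    Each masked pixel's full spectrum is SNV-transformed independently;
    unmasked pixels are left untouched.  Pixels whose spectrum is constant
    (SNV undefined) are dropped from the returned cube's mask and counted
    in a log summary.
    """
    from .cube import HyperCube  # local import: avoid module cycle

    if cube.kind != "reflectance":
        raise ValueError("snv_cube expects a reflectance cube")
    if mask is None:
        mask = cube.mask
    if mask is None or not np.any(mask):
        raise ValueError("snv_cube needs a non-empty mask")

    data = cube.data.astype(float, copy=True)
    pix = data[mask]                       # n_masked x B
    sd = pix.std(axis=1)
    ok = np.isfinite(sd) & (sd > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("snv_cube: dropped %d constant-spectrum pixel(s) from mask",
                    n_dropped)
    out_mask = mask.copy()
    out_mask[mask] = ok
    pix_ok = pix[ok]
    pix_ok = (pix_ok - pix_ok.mean(axis=1, keepdims=True)) / sd[ok][:, None]
    data[out_mask] = pix_ok
    return HyperCube(data=data, grid=cube.grid, kind="reflectance", mask=out_mask)
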