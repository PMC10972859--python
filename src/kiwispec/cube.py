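"""Hypercube container, reflectance calibration, ROI segmentation.

Raw push-broom counts are converted to relative reflectance against
per-pixel dark-current and white-reference frames:

    R = (raw - dark) / (white - dark)

computed per pixel and band.  Pixels whose white-dark dynamic range is
not usably positive are excluded from the mask rather than clipped, so
no information is silently distorted.  The fruit region of interest is
then segmented by thresholding a near-infrared band, where the fruit is
bright against the dark background, and keeping the largest connected
component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import WavelengthGrid
from . import envi

log = logging.getLogger(__name__)

#: default ROI segmentation band (nm) and reflectance threshold
SEGMENT_BAND_NM = 800.0
SEGMENT_THRESHOLD = 0.15


@dataclass
class HyperCube:
    """H x W x B raster with its wavelength axis.

    ``kind`` distinguishes raw detector counts from calibrated
    reflectance; models only ever see reflectance.  ``mask`` flags fruit
    pixels (True) and is shared row-major with ``data``.
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"          # "raw" | "reflectance"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H x W x B")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"band axis ({self.data.shape[2]}) != grid length ({len(self.grid)})"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError("kind must be 'raw' or 'reflectance'")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask geometry does not match cube")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_mask(self, mask: np.ndarray) -> "HyperCube":
        return replace(self, mask=mask)

    def save(self, path: str) -> None:
        envi.write_cube(path, self.data, self.grid.wavelengths,
                        dtype=np.float32)

    @classmethod
    def load(cls, path: str, kind: str = "raw",
             grid: WavelengthGrid | None = None) -> "HyperCube":
        data, wav = envi.read_cube(path)
        if grid is None:
            if wav is None:
                raise ValueError(f"{path}: header has no wavelengths and no "
                                 "grid was supplied")
            grid = WavelengthGrid(wav)
        return cls(data=data, grid=grid, kind=kind)


@dataclass
class ReferenceFrames:
    """White-reference and dark-current frames matching a cube's geometry."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames differ in geometry")


def calibrate_reflectance(raw: HyperCube, frames: ReferenceFrames,
                          epsilon: float = 1e-6) -> HyperCube:
    """Dark/white reflectance correction: R = (raw - dark)/(white - dark).

    Pixels where the white-dark difference is <= ``epsilon`` at any band
    are flagged invalid and excluded from the output mask instead of
    producing unstable ratios.
    """
    if raw.kind != "raw":
        raise ValueError("calibrate_reflectance expects a raw-counts cube")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    for axis, name in enumerate(("lines", "samples", "bands")):
        if frames.white.shape[axis] != raw.data.shape[axis]:
            raise ValueError(
                f"reference frame geometry mismatch on the {name} axis: "
                f"{frames.white.shape[axis]} != {raw.data.shape[axis]}"
            )

    denom = frames.white - frames.dark
    usable = np.all(denom > epsilon, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data.astype(float) - frames.dark) / denom
    refl[~usable] = np.nan

    mask = usable if raw.mask is None else (raw.mask & usable)
    n_bad = int((~usable).sum())
    if n_bad:
        log.info("calibrate_reflectance: %d pixel(s) had unusable white-dark "
                 "range and were masked out", n_bad)
    return HyperCube(data=refl, grid=raw.grid, kind="reflectance", mask=mask)


def segment_roi(cube: HyperCube, threshold: float = SEGMENT_THRESHOLD,
                band_nm: float = SEGMENT_BAND_NM) -> np.ndarray:
    """Threshold a near-infrared band and keep the largest connected blob.

    Returns a boolean H x W fruit mask.  ``threshold`` is in reflectance
    units and must lie in (0, 1); the fruit is bright at ``band_nm``
    while the imaging background stays dark.
    """
    if cube.kind != "reflectance":
        raise ValueError("segment_roi expects a reflectance cube")
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    band = cube.grid.index_of(band_nm)
    plane = cube.data[:, :, band]
    cand = np.isfinite(plane) & (plane > threshold)
    if cube.mask is not None:
        cand &= cube.mask
    if not cand.any():
        warnings.warn("segment_roi: no pixel exceeded the threshold; "
                      "empty mask returned", stacklevel=2)
        return cand
    labels, n = ndimage.label(cand)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        cand = labels == (1 + int(np.argmax(sizes)))
    return cand


def mean_spectrum(cube: HyperCube, mask: np.ndarray | None = None) -> np.ndarray:
    """Arithmetic mean spectrum over the masked pixels, one value per band."""
    if mask is None:
        mask = cube.mask
    if mask is None or not np.any(mask):
        raise ValueError("mean_spectrum needs a non-empty mask")
    return cube.data[np.asarray(mask, dtype=bool)].mean(axis=0)
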