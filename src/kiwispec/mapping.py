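"""Pixel-wise model application and pseudo-color distribution maps.

Every masked pixel's full-band spectrum is SNV-transformed and fed
through a calibrated model, giving a spatial map of the predicted index
in physical units.  Maps are rendered through a matplotlib colormap over
an explicit display range so that several maps (e.g. one per maturity
stage) can share one value-to-color scale; out-of-range values clip to
the endpoints and background pixels render neutral gray.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps
from PIL import Image

from .cube import HyperCube
from .models import CalibratedModel, predict
from .preprocess import snv_cube

DEFAULT_COLORMAP = "viridis"
BACKGROUND_RGB = (128, 128, 128)
#: default shared-range policy: central 95% across a batch of maps
RANGE_PERCENTILES = (2.5, 97.5)


@dataclass
class PredictionMap:
    """H x W predicted index values over a fruit mask."""

    values: np.ndarray
    mask: np.ndarray
    index: str
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask geometry differ")

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def predict_map(cube: HyperCube, model: CalibratedModel,
                mask: np.ndarray | None = None) -> PredictionMap:
    """Apply a calibrated model to every masked pixel of a reflectance cube.

    SNV runs on each pixel's full-band spectrum first; constant-spectrum
    pixels are dropped from the mask.  Unmasked pixels carry NaN.
    """
    if mask is None:
        mask = cube.mask
    if mask is None or not np.any(mask):
        raise ValueError("predict_map needs a non-empty mask")
    prepped = snv_cube(cube, mask)
    out_mask = prepped.mask
    values = np.full(cube.data.shape[:2], np.nan)
    pix = prepped.data[out_mask]
    values[out_mask] = predict(model, pix, grid=cube.grid)
    return PredictionMap(values=values, mask=out_mask,
                         index=model.target, units=model.units)


def shared_range(maps, percentiles=RANGE_PERCENTILES) -> tuple[float, float]:
    """Display range covering the central mass of a batch of maps."""
    pooled = np.concatenate([m.masked_values for m in maps])
    lo, hi = np.percentile(pooled, percentiles)
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo == hi:
        raise ValueError("degenerate display range")
    return float(lo), float(hi)


def render_pseudocolor(pmap: PredictionMap,
                       vrange: tuple[float, float],
                       colormap: str = DEFAULT_COLORMAP) -> np.ndarray:
    """Render a map to an H x W x 3 uint8 image.

    Values map linearly onto the colormap over ``vrange``; out-of-range
    values clip to the endpoints; background pixels are neutral gray.
    Rendering is a pure function of (values, range, colormap).
    """
    lo, hi = vrange
    if not (np.isfinite(lo) and np.isfinite(hi)) or not lo < hi:
        raise ValueError("display range must be finite with low < high")
    cmap = colormaps[colormap]
    t = np.clip((pmap.values - lo) / (hi - lo), 0.0, 1.0)
    t = np.nan_to_num(t, nan=0.0)
    rgb = (cmap(t)[..., :3] * 255).round().astype(np.uint8)
    rgb[~pmap.mask] = BACKGROUND_RGB
    return rgb


def save_map(pmap: PredictionMap, out_dir: str, stem: str,
             vrange: tuple[float, float],
             colormap: str = DEFAULT_COLORMAP) -> dict:
    """Persist one map: PNG image, CSV of raw values, JSON sidecar.

    The sidecar records the colorbar range, colormap and units, so the
    rendering is reproducible bit-for-bit from the artifacts.
    """
    os.makedirs(out_dir, exist_ok=True)
    rgb = render_pseudocolor(pmap, vrange, colormap)
    png = os.path.join(out_dir, f"{stem}.png")
    Image.fromarray(rgb).save(png)
    csv = os.path.join(out_dir, f"{stem}.csv")
    pd.DataFrame(pmap.values).to_csv(csv, index=False)
    meta = {"index": pmap.index, "units": pmap.units,
            "range": [vrange[0], vrange[1]], "colormap": colormap,
            "n_masked": int(pmap.mask.sum())}
    with open(os.path.join(out_dir, f"{stem}.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return meta
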