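"""Synthetic kiwifruit hyperspectral data with known ground truth.

Real orchard campaigns of this kind (four harvest batches at increasing
maturity, 50 fruit per batch) are rarely deposited, so every downstream
stage is exercised on simulated data built from a small physical model:

* each fruit carries latent "concentrations" of three absorbing
  components — a chlorophyll-like pigment (absorption near 675 nm), water
  (near 980 nm) and a ripeness pigment (near 560 nm);
* reflectance = gain x (baseline - sum_k conc_k x absorption_k) + offset
  + noise, i.e. smooth baseline minus scaled absorption dips, wrapped in
  exactly the multiplicative/additive scatter that SNV removes;
* each physicochemical index (SSC, firmness, L*, a*, b*) is an affine
  function of the concentrations plus measurement noise.  Soluble solid
  content is drawn uniformly from the per-stage deg-Brix intervals of the
  emulated campaign (unripe 4.63-5.73, semi-ripe 5.90-7.30, ripe
  6.50-9.20, over-ripe 9.20-12.20), so stage-mean SSC increases with
  maturity while firmness, coupled to the declining chlorophyll pool,
  decreases.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import WavelengthGrid, default_grid
from .cube import HyperCube, ReferenceFrames
from . import envi

#: canonical physicochemical index names and units, in reporting order
INDEX_NAMES = ("SSC", "firmness", "L*", "a*", "b*")
INDEX_UNITS = {"SSC": "°Brix", "firmness": "kg·cm⁻²",
               "L*": "", "a*": "", "b*": ""}

#: per-stage SSC intervals (°Brix) of the emulated four-batch harvest
STAGE_SSC_RANGES = ((4.63, 5.73), (5.90, 7.30), (6.50, 9.20), (9.20, 12.20))
STAGE_NAMES = ("unripe", "semi-ripe", "ripe", "over-ripe")


@dataclass(frozen=True)
class SimulationConfig:
    """All generator knobs, with the emulated campaign as defaults."""

    n_per_stage: int = 50
    stage_ssc_ranges: tuple = STAGE_SSC_RANGES
    # endmember absorption peaks: (center nm, sigma nm, peak amplitude)
    endmember_peaks: tuple = ((675.0, 28.0, 0.22),   # chlorophyll-like
                              (980.0, 40.0, 0.18),   # water
                              (560.0, 45.0, 0.15))   # ripeness pigment
    # per-stage latent means for (chlorophyll, water); the ripeness pigment
    # is slaved to the drawn SSC through the coupling below
    stage_chl_means: tuple = (1.00, 0.85, 0.70, 0.55)
    stage_water_means: tuple = (1.0, 1.0, 1.0, 1.0)
    chl_sd: float = 0.06
    water_sd: float = 0.05
    # index = intercept + a·chl + b·water + c·pigment  (+ noise)
    coupling: tuple = (
        ("SSC",      2.4,  0.0,  0.0,  7.0),
        ("firmness", 8.4, 13.0,  0.0, -1.0),
        ("L*",       26.3, -6.0, 20.0,  0.0),
        ("a*",       8.8, -2.0,  0.0,  2.8),
        ("b*",       9.1,  0.0,  8.0,  4.0),
    )
    index_noise_sd: tuple = (0.15, 0.5, 0.4, 0.15, 0.3)
    # multiplicative/additive scatter (the class SNV removes) and band noise
    gain_range: tuple = (0.95, 1.05)
    offset_range: tuple = (-0.02, 0.02)
    noise_sd: float = 0.002
    # smooth per-sample continuum variability NOT removable by SNV
    # (Legendre perturbations; why wavelength selection helps)
    continuum_sd: float = 0.01
    continuum_degrees: tuple = (2, 3, 4, 5)
    # cube generation
    cube_gain_sd: float = 0.04
    cube_count_noise_sd: float = 5.0
    background_reflectance: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_stage < 2:
            raise ValueError("need at least 2 samples per stage "
                             "(standard deviations are undefined otherwise)")
        for lo, hi in self.stage_ssc_ranges:
            if not hi > lo:
                raise ValueError("every stage SSC range must be non-empty")
        if self.noise_sd < 0 or self.cube_count_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic generation")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    concentrations: pd.DataFrame          # samples x latent components
    coupling: pd.DataFrame                # index -> intercept + slopes
    informative_bands: np.ndarray         # band indices carrying signal
    stages: pd.Series                     # sample id -> stage name
    endmembers: np.ndarray                # components x bands
    baseline: np.ndarray                  # length B


def baseline_spectrum(grid: WavelengthGrid) -> np.ndarray:
    """Smooth low-order-polynomial reflectance continuum in [0.2, 0.8]."""
    lo, hi = grid.span
    t = (grid.wavelengths - lo) / (hi - lo)
    return 0.35 + 0.6 * t - 0.17 * t ** 2


def make_endmembers(grid: WavelengthGrid,
                    config: SimulationConfig | None = None) -> np.ndarray:
    """Gaussian absorption profiles, one row per component.

    Rows are non-negative and peak at the grid point nearest the
    configured centers (chlorophyll near 675 nm, water near 980 nm by
    default).  Deterministic given the config.
    """
    config = config or SimulationConfig()
    lo, hi = grid.span
    out = np.empty((len(config.endmember_peaks), len(grid)))
    for k, (center, sigma, amp) in enumerate(config.endmember_peaks):
        if not (lo <= center <= hi):
            raise ValueError(
                f"endmember peak at {center} nm lies outside the grid span "
                f"[{lo}, {hi}] nm"
            )
        out[k] = amp * np.exp(-0.5 * ((grid.wavelengths - center) / sigma) ** 2)
    return out


def informative_bands(endmembers: np.ndarray) -> np.ndarray:
    """Band indices where any component exceeds half of its own maximum."""
    rel = endmembers / endmembers.max(axis=1, keepdims=True)
    return np.flatnonzero((rel > 0.5).any(axis=0))


def simulate_samples(config: SimulationConfig | None = None,
                     grid: WavelengthGrid | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a full campaign: spectra table, reference table, ground truth.

    Returns row-aligned DataFrames indexed by sample id: spectra
    (N x B reflectance, columns = band centers in nm) and reference
    indices (N x 5, columns = ``INDEX_NAMES``).
    """
    config = config or SimulationConfig()
    config.validate()
    grid = grid or default_grid()
    rng = np.random.default_rng(config.seed)

    E = make_endmembers(grid, config)
    base = baseline_spectrum(grid)
    coup = pd.DataFrame(
        [row[1:] for row in config.coupling],
        index=[row[0] for row in config.coupling],
        columns=["intercept", "chl", "water", "pigment"], dtype=float)

    n_stages = len(config.stage_ssc_ranges)
    n = config.n_per_stage * n_stages
    ids = [f"S{i + 1:03d}" for i in range(n)]
    stages = pd.Series(np.repeat(STAGE_NAMES[:n_stages], config.n_per_stage),
                       index=ids, name="stage")

    # latent concentrations
    m_ssc = coup.loc["SSC", "pigment"]
    b_ssc = coup.loc["SSC", "intercept"]
    ssc_true = np.concatenate([
        rng.uniform(lo, hi, config.n_per_stage)
        for lo, hi in config.stage_ssc_ranges])
    pigment = (ssc_true - b_ssc) / m_ssc
    chl = np.concatenate([
        rng.normal(m, config.chl_sd, config.n_per_stage)
        for m in config.stage_chl_means[:n_stages]])
    water = np.concatenate([
        rng.normal(m, config.water_sd, config.n_per_stage)
        for m in config.stage_water_means[:n_stages]])
    conc = pd.DataFrame(
        np.clip(np.column_stack([chl, water, pigment]), 0.0, None),
        index=ids, columns=["chl", "water", "pigment"])

    # reference indices: affine in the concentrations, plus noise
    design = np.column_stack([np.ones(n), conc.to_numpy()])
    ref = design @ coup.to_numpy().T
    ref += rng.normal(0.0, config.index_noise_sd, size=(n, len(coup)))
    reference = pd.DataFrame(ref, index=ids, columns=list(coup.index))

    # spectra: scatter-wrapped mixture of baseline minus absorption dips,
    # plus smooth per-sample continuum perturbations (SNV cannot remove
    # these; they are what makes wavelength selection worthwhile)
    clean = base[None, :] - conc.to_numpy() @ E
    if config.continuum_sd > 0:
        from numpy.polynomial import legendre
        t = np.linspace(-1.0, 1.0, len(grid))
        P = np.stack([legendre.Legendre.basis(d)(t)
                      for d in config.continuum_degrees])
        clean = clean + rng.normal(
            0.0, config.continuum_sd, size=(n, P.shape[0])) @ P
    gain = rng.uniform(*config.gain_range, size=(n, 1))
    offset = rng.uniform(*config.offset_range, size=(n, 1))
    spectra = gain * clean + offset
    if config.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, config.noise_sd,
                                       size=spectra.shape)
    spectra_df = pd.DataFrame(spectra, index=ids,
                              columns=np.round(grid.wavelengths, 2))

    truth = GroundTruth(concentrations=conc, coupling=coup,
                        informative_bands=informative_bands(E),
                        stages=stages, endmembers=E, baseline=base)
    return spectra_df, reference, truth


def _ellipse_mask(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    ry, rx = 0.42 * h, 0.42 * w
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def simulate_cube(spectrum: np.ndarray, shape: tuple[int, int],
                  config: SimulationConfig | None = None,
                  grid: WavelengthGrid | None = None,
                  seed: int | None = None,
                  ) -> tuple[HyperCube, ReferenceFrames, np.ndarray]:
    """Raw-counts cube plus dark/white frames for one fruit.

    Foreground pixels (an inscribed ellipse) carry ``spectrum`` with
    per-pixel gain and count noise; background pixels carry a low flat
    reflectance.  Raw counts are synthesized as
    ``dark + R x (white - dark)``, so dark/white reflectance correction
    inverts the construction exactly in the noiseless limit.

    Returns (raw cube, reference frames, true fruit mask).
    """
    config = config or SimulationConfig()
    config.validate()
    grid = grid or default_grid()
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != (len(grid),):
        raise ValueError("sample spectrum must lie on the grid")
    h, w = shape
    if h == 0 or w == 0:
        raise ValueError("cube shape must have non-zero dimensions")
    if h < 8 or w < 8:
        raise ValueError("cube shape must be at least 8 x 8")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    mask = _ellipse_mask((h, w))
    refl = np.full((h, w, len(grid)), config.background_reflectance)
    gain = rng.normal(1.0, config.cube_gain_sd, size=(h, w, 1))
    refl[mask] = (gain[mask] * spectrum[None, :])

    # smooth band-dependent illumination for the white frame
    t = np.linspace(-1.0, 1.0, len(grid))
    illum = 1.0 - 0.3 * t ** 2
    dark = np.full((h, w, len(grid)), 100.0)
    white = dark + 3900.0 * illum[None, None, :]

    raw = dark + refl * (white - dark)
    if config.cube_count_noise_sd > 0:
        raw = raw + rng.normal(0.0, config.cube_count_noise_sd, size=raw.shape)

    cube = HyperCube(data=raw, grid=grid, kind="raw")
    return cube, ReferenceFrames(white=white, dark=dark), mask


# ---------------------------------------------------------------------------
# plain-text persistence

def write_tables(out_dir: str, spectra: pd.DataFrame,
                 reference: pd.DataFrame) -> tuple[str, str]:
    """Write spectra and reference tables as CSV; returns their paths."""
    os.makedirs(out_dir, exist_ok=True)
    sp = os.path.join(out_dir, "spectra.csv")
    rp = os.path.join(out_dir, "reference.csv")
    spectra.to_csv(sp, index_label="sample_id")
    reference.to_csv(rp, index_label="sample_id")
    return sp, rp


def read_spectra_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    df.columns = df.columns.astype(float)
    return df


def read_reference_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_cube_bundle(out_dir: str, name: str, cube: HyperCube,
                      frames: ReferenceFrames) -> None:
    """Persist a raw cube plus its frames as ENVI-style rasters."""
    os.makedirs(out_dir, exist_ok=True)
    cube.save(os.path.join(out_dir, f"{name}_raw.img"))
    envi.write_cube(os.path.join(out_dir, f"{name}_white.img"), frames.white,
                    cube.grid.wavelengths)
    envi.write_cube(os.path.join(out_dir, f"{name}_dark.img"), frames.dark,
                    cube.grid.wavelengths)
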