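# Methods

This note records the models, conventions and design choices behind
`kiwispec`, in the order the pipeline runs them.

## Wavelength axis

All spectra share a 256-band axis spanning 390–1030 nm (mean sampling
interval ≈ 2.51 nm). Visible/near-infrared imaging spectrographs of
this class have a mildly nonlinear dispersion, and the published
feature-wavelength lists the package ships are inconsistent with a
uniform grid: 22 of the listed band centers (e.g. 439, 449, 617 nm)
fall more than 1 nm from any point of a 256-point linspace. The default
axis is therefore reconstructed as a monotone PCHIP interpolant through
the reported band centers, assigned to band indices by a monotone fit
against a smooth cubic dispersion model and pinned to 390/1030 nm at
the ends. Every published wavelength is then an exact band center, and
`WavelengthGrid.index_of(nm, tol=1.0)` resolves model wavelengths by
nearest neighbor with a 1 nm guard. Custom axes (any strictly
increasing vector) are supported throughout.

## Synthetic campaign generator

The generator exists so that every stage of the workflow is testable
against known ground truth. One simulated campaign mirrors a four-batch
harvest: four maturity stages, 50 fruit each, with per-stage SSC drawn
uniformly from 4.63–5.73, 5.90–7.30, 6.50–9.20 and 9.20–12.20 °Brix.

**Spectral model.** Each fruit carries latent concentrations of three
absorbers: a chlorophyll-like pigment (Gaussian absorption centered at
675 nm, σ = 28 nm, amplitude 0.22), water (980 nm, σ = 40 nm, 0.18) and
a ripeness pigment (560 nm, σ = 45 nm, 0.15). Reflectance is

    r = gain · (baseline − Σₖ concₖ · absorptionₖ + continuum) + offset + ε

with a low-order polynomial baseline in [0.35, 0.78], gain ~ U(0.95,
1.05), offset ~ U(−0.02, 0.02) and iid band noise ε with sd 0.002. The
gain/offset wrap is exactly the affine class SNV removes (a property
test asserts this); the *continuum* term is a random degree-2–5
Legendre perturbation (sd 0.01 per coefficient) that SNV cannot remove.
The continuum term is what gives wavelength selection its purpose: with
iid noise alone, a cross-validated full-spectrum PLSR is never hurt by
uninformative bands and the CARS error trajectory stays flat instead of
showing the characteristic dip.

**Index couplings.** Chlorophyll declines with stage (means 1.00 →
0.55, sd 0.06), water stays at 1.0 (sd 0.05), and the ripeness pigment
is slaved to the drawn SSC through the SSC coupling row (SSC = 2.4 +
7.0·pigment). Each index is affine in the latents plus Gaussian
measurement noise; the default coupling matrix makes stage-mean SSC
strictly increase and firmness strictly decrease, and keeps pooled
values inside realistic spans (firmness ≈ 12–24 kg·cm⁻², L\* ≈ 37–46,
a\* ≈ 7–12, b\* ≈ 15–25). The per-stage distributions of firmness and
color are not reported anywhere for this kind of campaign, so the
couplings are a modeling choice of this package, not a literature
claim.

**Ground truth.** Informative bands are defined as the bands where any
absorption profile exceeds 50% of its own maximum (104 of 256 bands
under the defaults) — an unambiguous target for selector-recovery
tests. Cubes are synthesized as raw counts = dark + R·(white − dark)
with an elliptical fruit mask, per-pixel gain (sd 0.04) and count noise
(sd 5), so the reflectance correction inverts the construction exactly
in the noiseless limit.

**What the generator does not emulate:** real tissue optics, specular
highlights, spatial texture within a fruit, wavelength-dependent noise,
and the actual covariance structure of orchard fruit. Passing tests
demonstrate that the algorithms are implemented correctly and behave as
expected under a controlled spectral model — not that the models would
reach any particular accuracy on real fruit.

## Preprocessing

SNV divides by the **population** standard deviation (÷B). The
convention matters because published model coefficients are
scale-sensitive, and it is applied uniformly. SNV always acts on the
full 256-band spectrum *before* any band subsetting — selection,
fitting and mapping all receive full-spectrum SNV values; a regression
test asserts that subsetting first would change the values. Constant
spectra (sd = 0) raise `ConstantSpectrumError`; in pixel-wise use such
pixels are dropped from the mask and counted in a log summary.

## Reflectance calibration and ROI

R = (raw − dark)/(white − dark) per pixel and band. Values are **not**
clipped to [0, 1]; pixels whose white−dark range is ≤ ε (default 1e−6)
at any band are excluded from the mask instead, which preserves
information and avoids silent distortion. The ROI is segmented by
thresholding the band nearest 800 nm at 0.15 reflectance (fruit is
bright in the NIR against a dark background) and keeping the largest
connected component; both knobs are arguments. ENVI-style I/O writes
BIL and reads BIL/BIP/BSQ with the header fields samples/lines/bands/
interleave/data type/wavelength.

## SPXY partitioning

Joint distance d = dₓ/max dₓ + d_y/max d_y with Euclidean dₓ on SNV
spectra and Euclidean d_y on per-index autoscaled reference values, all
five indices jointly (one partition serves all indices). Selection is
Kennard–Stone max–min seeded with the globally most distant pair; ties
break toward the smallest sample position, making the split fully
deterministic and permutation-invariant. The first n_cal selections
form the calibration set (140/60 at the default campaign size).

## CARS

Defaults: 50 Monte Carlo runs, 5-fold RMSECV, subset ratio 0.8.
Per run i: (a) draw the subset; (b) fit a PLSR on the retained
wavelengths, latent variables capped at min(10, rank) and chosen by
inner 5-fold RMSECV; (c) weight each wavelength by |b| from the
explicit regression vector; (d) shrink the keep-count along the
exponentially decreasing schedule rᵢ = a·e^(−k·i) with r₁ = 1 and
r_N = 2/B (so k = ln(B/2)/(N−1)); (e) realize the retained set by B
weighted draws with replacement, deduplicated — a wavelength survives
if drawn at least once; (f) record the 5-fold RMSECV of a PLSR on the
retained set over the whole calibration set. The winner is the run with
minimum RMSECV; `max_selected` can exclude runs too large for a
downstream MLR (their RMSECV stays in the trajectory). Everything is
deterministic given (data, seed).

## SPA

For every candidate start band a chain is grown by adding the band with
the largest residual norm after orthogonal projection onto the span of
the selected columns (collinear bands get residual ≈ 0 and can never
follow their twin). Chain prefixes are scored by k-fold (default
5-fold, unshuffled) cross-validated MLR RMSE; growth stops when the
relative improvement drops below 1% or the error is already numerically
zero (absolute floor 1e−10, which makes the noiseless limit terminate).
Among starts, the winner is the lowest (RMSE, size, start) triple —
fully deterministic. A brute-force oracle over all (start, size)
combinations is part of the permanent test suite.

## Models

MLR is ordinary least squares with an intercept; rank-deficient designs
are rejected with the collinear wavelengths named, as are
under-determined fits (n ≤ m + 1). PLSR uses NIPALS (via
scikit-learn's `PLSRegression`, no autoscaling beyond SNV) with the
latent-variable count chosen by k-fold RMSECV over 1..min(15, rank);
the fitted model is exported in explicit linear form (intercept + one
coefficient per band), which is also the |b| vector CARS consumes. y is
kept in physical units so coefficients are comparable with the
published equations. Models serialize to JSON with their preprocessing
tag (`snv-full-spectrum`); `predict` refuses spectra whose tag or grid
does not match.

The published CARS-MLR equations are stored to their printed decimal
precision only, so predictions from those fixtures are approximate to
that precision and demonstrative by nature (whether their SNV used
population or sample sd is not recoverable).

## Evaluation

R² = 1 − SSres/SStot around the evaluated set's own mean (for both
sets; R² can be negative for a bad model). RMSE uses 1/n. RPD =
SD/RMSEP where SD is the **sample** (n−1) standard deviation of the
prediction-set reference values — this convention reproduces reported
RPD values from their printed (SD, RMSEP) pairs at 2 dp. Quality bands:
< 1.4 below-poor, [1.4, 1.8) poor, [1.8, 2.0) good, ≥ 2.0 excellent.
Display rounding is decimal half-up to 2 dp; raw doubles are kept
internally.

## Mapping

Every masked pixel's full spectrum is SNV-transformed and pushed
through the model; failed (constant) pixels are dropped and counted.
The default display range for a batch of maps of one index is the
pooled 2.5th–97.5th percentile, shared across maturity stages so that
one color means one value in every image; out-of-range values clip to
the endpoints and background renders neutral gray. Rendering is a pure
function of (values, range, colormap) and the PNG output is bit-exact
reproducible. Because SNV is nonlinear, the ROI mean of the map does
not equal the model applied to the ROI-mean spectrum; a regression test
documents the (small) discrepancy rather than assuming equality.

## Pipeline and problem sizes

`run_pipeline` chains simulate → preprocess → split → select → fit →
evaluate → map, records per-stage wall-clock in a manifest together
with the config hash and seeds, and is byte-identical across reruns of
the same config. The test suite runs the generator at full campaign
scale (200 × 256) for partitioning, CARS behavior and mapping checks,
and at 4 × 5–6 fruit for pipeline smoke tests; selection oracles use
5-band instances where exhaustive search is feasible. These sizes were
chosen so the full suite completes in well under a minute of CPU apart
from the campaign-scale CARS check (a few seconds by itself).

## Known limitations

- The synthetic spectra are three-component Beer–Lambert-style mixtures;
  selector recovery rates on them (≈ 45% of selected bands inside the
  strict informative-band set for SSC) reflect that SNV and continuum
  variability smear information across bands, and should not be read as
  a field performance figure.
- CARS trajectories can truncate before the last run if fewer than two
  wavelengths survive resampling; the truncation is logged and the
  argmin is taken over completed runs.
- The published-model fixtures cannot be validated against real fruit
  here (no deposited data); they are exercised only through arithmetic
  identities and demonstrations and are labelled as such.
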