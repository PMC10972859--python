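import numpy as np
import pytest

import kiwispec as ks
from kiwispec.cube import HyperCube, calibrate_reflectance, segment_roi
from kiwispec.mapping import (PredictionMap, predict_map, render_pseudocolor,
                              shared_range, save_map)
from kiwispec.models import CalibratedModel, predict
from kiwispec.published import intercept_probe, load_published_model
from kiwispec.preprocess import snv
from kiwispec.synthetic import SimulationConfig, simulate_cube


@pytest.fixture()
def simple_model(grid):
    return CalibratedModel(family="MLR", intercept=2.0,
                           coefficients=np.array([1.5, -0.5]),
                           wavelengths_nm=np.array([675.0, 980.0]),
                           target="SSC", units="°Brix")


def _refl_cube(grid, data):
    return HyperCube(data=data, grid=grid, kind="reflectance")


def test_uniform_cube_gives_constant_map(grid, campaign, simple_model):
    spectra, _, _ = campaign
    s = spectra.iloc[0].to_numpy()
    cube = _refl_cube(grid, np.tile(s, (6, 6, 1)))
    pm = predict_map(cube, simple_model, np.ones((6, 6), bool))
    expected = predict(simple_model, snv(s), grid=grid)
    assert np.allclose(pm.values, expected)
    assert pm.index == "SSC" and pm.units == "°Brix"


def test_map_equals_per_pixel_loop(grid, campaign, simple_model):
    """Vectorized mapping == applying SNV+predict to each pixel alone."""
    spectra, _, _ = campaign
    rng = np.random.default_rng(0)
    data = np.stack([spectra.iloc[rng.integers(0, 200)].to_numpy()
                     for _ in range(12)]).reshape(3, 4, -1)
    cube = _refl_cube(grid, data)
    mask = np.ones((3, 4), bool)
    pm = predict_map(cube, simple_model, mask)
    for i in range(3):
        for j in range(4):
            ref = predict(simple_model, snv(data[i, j]), grid=grid)
            assert pm.values[i, j] == pytest.approx(ref, rel=1e-12)


def test_published_intercept_surfaces_in_map(grid):
    """A pixel whose SNV spectrum is zero at the 18 firmness model
    wavelengths maps to the printed intercept, 235.6."""
    model = load_published_model("firmness")
    probe = intercept_probe(model, grid)
    # build a raw spectrum whose SNV transform equals the probe
    raw = 0.5 + 0.01 * probe
    cube = _refl_cube(grid, np.tile(raw, (8, 8, 1)))
    pm = predict_map(cube, model, np.ones((8, 8), bool))
    assert np.allclose(pm.masked_values, 235.6)


def test_mean_of_map_differs_from_predict_on_mean_spectrum(grid, campaign,
                                                           simple_model):
    """SNV is nonlinear: mapping then averaging is NOT predicting on the
    ROI-mean spectrum. The discrepancy is real and documented here."""
    spectra, _, _ = campaign
    raw, frames, mask = simulate_cube(spectra.iloc[0].to_numpy(), (16, 16),
                                      SimulationConfig(seed=9), grid, seed=9)
    refl = calibrate_reflectance(raw, frames)
    pm = predict_map(refl, simple_model, mask)
    mean_spec = ks.mean_spectrum(refl, mask)
    via_mean = predict(simple_model, snv(mean_spec), grid=grid)
    via_map = float(np.nanmean(pm.masked_values))
    assert via_map != pytest.approx(via_mean, abs=1e-12)
    # but the two summaries agree to first order on a homogeneous fruit
    assert abs(via_map - via_mean) < 0.5


class TestRendering:
    def _map(self, values, mask=None):
        values = np.asarray(values, float)
        if mask is None:
            mask = np.isfinite(values)
        return PredictionMap(values=values, mask=mask, index="SSC")

    def test_constant_midpoint_is_uniform_mid_colormap(self):
        from matplotlib import colormaps
        pm = self._map(np.full((4, 4), 5.0))
        img = render_pseudocolor(pm, (0.0, 10.0))
        mid = (np.array(colormaps["viridis"](0.5)[:3]) * 255).round()
        assert (img == mid.astype(np.uint8)).all()

    def test_shared_range_means_shared_colors(self):
        pm1 = self._map(np.array([[1.0, 5.0]]))
        pm2 = self._map(np.array([[5.0, 9.0]]))
        img1 = render_pseudocolor(pm1, (0.0, 10.0))
        img2 = render_pseudocolor(pm2, (0.0, 10.0))
        assert (img1[0, 1] == img2[0, 0]).all()   # same value, same color

    def test_out_of_range_clips_and_background_is_gray(self):
        vals = np.array([[-5.0, 50.0], [np.nan, 5.0]])
        mask = np.array([[True, True], [False, True]])
        img = render_pseudocolor(self._map(vals, mask), (0.0, 10.0))
        lo = render_pseudocolor(self._map(np.array([[0.0]])), (0.0, 10.0))
        hi = render_pseudocolor(self._map(np.array([[10.0]])), (0.0, 10.0))
        assert (img[0, 0] == lo[0, 0]).all()
        assert (img[0, 1] == hi[0, 0]).all()
        assert (img[1, 0] == np.array([128, 128, 128], np.uint8)).all()

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            render_pseudocolor(self._map(np.ones((2, 2))), (3.0, 3.0))

    def test_rendering_is_pure(self):
        pm = self._map(np.array([[1.0, 2.0], [3.0, 4.0]]))
        a = render_pseudocolor(pm, (0.0, 5.0))
        b = render_pseudocolor(pm, (0.0, 5.0))
        assert np.array_equal(a, b)


def test_stage_series_maps_track_maturity(grid, campaign):
    """Across the four maturity stages, ROI-mean predicted SSC increases
    monotonically when all maps share one scale (frozen-seed check)."""
    spectra, reference, truth = campaign
    idx = truth.informative_bands[::8]
    snv_spec = ks.snv_table(spectra)
    model = ks.fit_mlr(snv_spec.to_numpy()[:, idx],
                       reference["SSC"].to_numpy(),
                       grid.wavelengths[idx], target="SSC", units="°Brix")
    means = []
    maps = []
    for s in range(4):
        sample = spectra.index[s * 50]
        raw, frames, _ = simulate_cube(spectra.loc[sample].to_numpy(),
                                       (24, 24), SimulationConfig(seed=0),
                                       grid, seed=100 + s)
        refl = calibrate_reflectance(raw, frames)
        pm = predict_map(refl, model, segment_roi(refl))
        maps.append(pm)
        means.append(float(np.nanmean(pm.masked_values)))
    assert all(np.diff(means) > 0)
    lo, hi = shared_range(maps)
    assert lo < hi


def test_save_map_artifacts(tmp_path, grid):
    pm = PredictionMap(values=np.array([[1.0, 2.0]]),
                       mask=np.array([[True, True]]), index="SSC",
                       units="°Brix")
    meta = save_map(pm, str(tmp_path), "m", (0.0, 5.0))
    assert (tmp_path / "m.png").exists()
    assert (tmp_path / "m.csv").exists()
    assert (tmp_path / "m.json").exists()
    assert meta["range"] == [0.0, 5.0]
    # bit-exact reproducibility of the PNG
    save_map(pm, str(tmp_path / "b"), "m", (0.0, 5.0))
    assert (tmp_path / "m.png").read_bytes() == \
        (tmp_path / "b" / "m.png").read_bytes()
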