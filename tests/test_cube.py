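import numpy as np
import pytest

import kiwispec as ks
from kiwispec import envi
from kiwispec.cube import (HyperCube, ReferenceFrames, calibrate_reflectance,
                           segment_roi, mean_spectrum)
from kiwispec.grid import WavelengthGrid
from kiwispec.synthetic import SimulationConfig, simulate_cube


@pytest.fixture()
def tiny_grid():
    return WavelengthGrid(np.array([500.0, 600.0, 700.0, 800.0]))


def _cube(data, grid, kind="raw"):
    return HyperCube(data=np.asarray(data, float), grid=grid, kind=kind)


class TestReflectanceCorrection:
    def test_raw_equals_white_gives_one(self, tiny_grid):
        white = np.full((4, 4, 4), 90.0)
        dark = np.full((4, 4, 4), 10.0)
        out = calibrate_reflectance(_cube(white, tiny_grid),
                                    ReferenceFrames(white=white, dark=dark))
        assert np.allclose(out.data, 1.0)
        assert out.kind == "reflectance"

    def test_raw_equals_dark_gives_zero(self, tiny_grid):
        white = np.full((4, 4, 4), 90.0)
        dark = np.full((4, 4, 4), 10.0)
        out = calibrate_reflectance(_cube(dark, tiny_grid),
                                    ReferenceFrames(white=white, dark=dark))
        assert np.allclose(out.data, 0.0)

    def test_midpoint_value(self, tiny_grid):
        out = calibrate_reflectance(
            _cube(np.full((4, 4, 4), 50.0), tiny_grid),
            ReferenceFrames(white=np.full((4, 4, 4), 90.0),
                            dark=np.full((4, 4, 4), 10.0)))
        assert np.allclose(out.data, 0.5)

    def test_scale_free(self, tiny_grid):
        rng = np.random.default_rng(1)
        dark = rng.uniform(5, 15, (4, 4, 4))
        white = dark + rng.uniform(50, 90, (4, 4, 4))
        raw = dark + rng.uniform(0, 1, (4, 4, 4)) * (white - dark)
        a = calibrate_reflectance(_cube(raw, tiny_grid),
                                  ReferenceFrames(white=white, dark=dark))
        c = 3.7
        b = calibrate_reflectance(_cube(c * raw, tiny_grid),
                                  ReferenceFrames(white=c * white,
                                                  dark=c * dark))
        assert np.allclose(a.data, b.data)

    def test_geometry_mismatch_names_axis(self, tiny_grid):
        raw = _cube(np.zeros((4, 4, 4)), tiny_grid)
        with pytest.raises(ValueError, match="lines"):
            calibrate_reflectance(raw, ReferenceFrames(
                white=np.ones((5, 4, 4)), dark=np.zeros((5, 4, 4))))

    def test_bad_denominator_pixels_masked(self, tiny_grid):
        white = np.full((4, 4, 4), 90.0)
        white[0, 0] = 10.0            # no dynamic range at this pixel
        dark = np.full((4, 4, 4), 10.0)
        out = calibrate_reflectance(_cube(np.full((4, 4, 4), 50.0), tiny_grid),
                                    ReferenceFrames(white=white, dark=dark))
        assert not out.mask[0, 0]
        assert out.mask.sum() == 15

    def test_requires_raw_kind(self, tiny_grid):
        refl = _cube(np.ones((4, 4, 4)), tiny_grid, kind="reflectance")
        with pytest.raises(ValueError, match="raw"):
            calibrate_reflectance(refl, ReferenceFrames(
                white=np.ones((4, 4, 4)), dark=np.zeros((4, 4, 4))))


class TestSegmentation:
    def test_recovers_generator_mask(self, grid, campaign):
        """On a default-noise synthetic fruit cube the NIR threshold mask
        matches the generator's ellipse on >=99% of pixels (frozen)."""
        spectra, _, _ = campaign
        raw, frames, true_mask = simulate_cube(
            spectra.iloc[0].to_numpy(), (32, 32),
            SimulationConfig(seed=0), grid, seed=7)
        refl = calibrate_reflectance(raw, frames)
        mask = segment_roi(refl)
        assert (mask == true_mask).mean() >= 0.99

    def test_background_only_cube_warns_and_is_empty(self, tiny_grid):
        cube = _cube(np.full((8, 8, 4), 0.02), tiny_grid, kind="reflectance")
        with pytest.warns(UserWarning, match="empty mask"):
            mask = segment_roi(cube, threshold=0.15, band_nm=800.0)
        assert not mask.any()

    def test_threshold_domain(self, tiny_grid):
        cube = _cube(np.full((8, 8, 4), 0.5), tiny_grid, kind="reflectance")
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError, match="threshold"):
                segment_roi(cube, threshold=bad)

    def test_largest_component_kept(self, tiny_grid):
        data = np.full((8, 8, 4), 0.01)
        data[1:6, 1:6] = 0.6          # big blob
        data[7, 7] = 0.6              # single stray pixel
        mask = segment_roi(_cube(data, tiny_grid, kind="reflectance"))
        assert mask[2, 2] and not mask[7, 7]


class TestMeanSpectrum:
    def test_constant_cube(self, tiny_grid):
        cube = _cube(np.full((4, 4, 4), 0.37), tiny_grid, kind="reflectance")
        assert np.allclose(mean_spectrum(cube, np.ones((4, 4), bool)), 0.37)

    def test_two_pixel_average(self, tiny_grid):
        data = np.zeros((2, 2, 4))
        data[0, 0] = 0.2
        data[0, 1] = 0.4
        mask = np.zeros((2, 2), bool)
        mask[0, :] = True
        out = mean_spectrum(_cube(data, tiny_grid, kind="reflectance"), mask)
        assert np.allclose(out, 0.3)

    def test_noiseless_cube_inverts_to_sample_spectrum(self, grid, campaign):
        spectra, _, _ = campaign
        s = spectra.iloc[3].to_numpy()
        cfg = SimulationConfig(seed=2, noise_sd=0.0, cube_count_noise_sd=0.0,
                               cube_gain_sd=0.0)
        raw, frames, mask = simulate_cube(s, (16, 16), cfg, grid)
        refl = calibrate_reflectance(raw, frames)
        assert np.allclose(mean_spectrum(refl, mask), s)

    def test_empty_mask_rejected(self, tiny_grid):
        cube = _cube(np.ones((4, 4, 4)), tiny_grid)
        with pytest.raises(ValueError, match="non-empty"):
            mean_spectrum(cube, np.zeros((4, 4), bool))


class TestEnviRoundTrip:
    def test_write_read_exact(self, tmp_path, tiny_grid):
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 1, (5, 6, 4)).astype(np.float32)
        path = str(tmp_path / "cube.img")
        envi.write_cube(path, data, tiny_grid.wavelengths)
        back, wav = envi.read_cube(path)
        assert np.array_equal(back, data)
        assert np.array_equal(wav, tiny_grid.wavelengths)

    @pytest.mark.parametrize("interleave", ["bil", "bip", "bsq"])
    def test_all_interleaves_read_identically(self, tmp_path, interleave):
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 1, (3, 4, 5)).astype(np.float32)
        raw = {"bil": data.transpose(0, 2, 1),
               "bip": data,
               "bsq": data.transpose(2, 0, 1)}[interleave]
        path = tmp_path / "c.img"
        raw.tofile(str(path))
        hdr = ("ENVI\nsamples = 4\nlines = 3\nbands = 5\ndata type = 4\n"
               f"interleave = {interleave}\nbyte order = 0\n")
        (tmp_path / "c.img.hdr").write_text(hdr)
        back, _ = envi.read_cube(str(path))
        assert np.array_equal(back, data)

    def test_size_mismatch_detected(self, tmp_path):
        np.zeros(10, np.float32).tofile(str(tmp_path / "c.img"))
        (tmp_path / "c.img.hdr").write_text(
            "ENVI\nsamples = 4\nlines = 3\nbands = 5\ndata type = 4\n"
            "interleave = bil\n")
        with pytest.raises(ValueError, match="header implies"):
            envi.read_cube(str(tmp_path / "c.img"))
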