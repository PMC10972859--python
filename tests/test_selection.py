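import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

import kiwispec as ks
from kiwispec.grid import WavelengthGrid
from kiwispec.selection import (cars_select, edf_counts, spa_chain,
                                spa_plateau_size, spa_select,
                                SPA_PLATEAU_ABS, SPA_PLATEAU_REL)
from kiwispec.published import (load_published_wavelengths,
                                wavelength_proportion_pct,
                                PUBLISHED_WAVELENGTHS)
from kiwispec.synthetic import simulate_samples


class TestEdfSchedule:
    def test_boundary_and_monotonicity(self):
        counts = edf_counts(256, 50)
        assert counts[0] == 256                    # run 1 keeps every band
        assert counts[-1] == 2
        assert np.all(np.diff(counts) <= 0)

    def test_small_instance(self):
        counts = edf_counts(10, 5)
        assert counts[0] == 10 and counts[-1] == 2
        assert np.all(counts >= 2)


class TestCars:
    def _data(self, seed=0, n=60, n_bands=40):
        """Few informative bands drive y; the rest is smooth noise."""
        rng = np.random.default_rng(seed)
        grid = WavelengthGrid(np.linspace(400, 900, n_bands))
        conc = rng.normal(size=(n, 2))
        prof = np.zeros((2, n_bands))
        prof[0, 8:12] = [0.5, 1.0, 1.0, 0.5]
        prof[1, 25:29] = [0.5, 1.0, 1.0, 0.5]
        X = 0.5 + conc @ prof * 0.1 + rng.normal(0, 0.01, (n, n_bands))
        y = 3.0 + 2.0 * conc[:, 0] - 1.5 * conc[:, 1] + rng.normal(0, 0.05, n)
        return X, y, grid

    def test_deterministic_given_seed(self):
        X, y, grid = self._data()
        a = cars_select(X, y, grid, n_runs=15, n_folds=3, seed=5)
        b = cars_select(X, y, grid, n_runs=15, n_folds=3, seed=5)
        assert np.array_equal(a.selected_idx, b.selected_idx)
        assert np.allclose(a.trajectory, b.trajectory, equal_nan=True)

    def test_selected_are_valid_band_subset(self):
        X, y, grid = self._data()
        res = cars_select(X, y, grid, n_runs=15, n_folds=3, seed=5)
        assert res.method == "CARS"
        assert np.array_equal(res.selected_idx, np.unique(res.selected_idx))
        assert res.selected_idx.min() >= 0
        assert res.selected_idx.max() < len(grid)
        assert np.allclose(res.selected_nm,
                           grid.wavelengths[res.selected_idx])

    def test_retained_counts_non_increasing(self):
        X, y, grid = self._data()
        res = cars_select(X, y, grid, n_runs=15, n_folds=3, seed=5)
        counts = res.retained_counts[res.retained_counts > 0]
        assert np.all(np.diff(counts) <= 0)

    def test_max_selected_constrains_winner(self):
        X, y, grid = self._data()
        res = cars_select(X, y, grid, n_runs=15, n_folds=3, seed=5,
                          max_selected=10)
        assert res.n_selected <= 10

    def test_too_few_samples_rejected(self):
        X, y, grid = self._data(n=8)
        with pytest.raises(ValueError, match="calibration samples"):
            cars_select(X, y, grid, n_runs=10, n_folds=5, seed=0)


class TestSpa:
    def test_duplicated_column_never_follows_twin(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(20, 5))
        X[:, 3] = X[:, 1]                       # exact twin
        chain = spa_chain(X, start=1, max_size=5)
        assert 3 not in chain
        chain2 = spa_chain(X, start=3, max_size=5)
        assert 1 not in chain2

    def test_matches_exhaustive_oracle(self):
        """5-band, 12-sample instance against an independent brute-force
        search over every (start, size), scored by the same CV RMSE."""
        rng = np.random.default_rng(7)
        grid = WavelengthGrid(np.linspace(500, 900, 5))
        X = rng.uniform(0.2, 0.8, (12, 5))
        y = 1.0 + X @ rng.normal(size=5) + rng.normal(0, 0.05, 12)
        n_folds = 3

        def oracle_chain(start, max_size):
            sel = [start]
            while len(sel) < max_size:
                best_n, best_j = -1.0, None
                for j in range(5):
                    if j in sel:
                        continue
                    A = X[:, sel]
                    r = X[:, j] - A @ np.linalg.lstsq(A, X[:, j],
                                                      rcond=None)[0]
                    if np.linalg.norm(r) > best_n:
                        best_n, best_j = np.linalg.norm(r), j
                if best_n <= 1e-10:
                    break
                sel.append(best_j)
            return sel

        def oracle_rmse(cols):
            folds = np.array_split(np.arange(12), n_folds)
            press = 0.0
            for te in folds:
                tr = np.setdiff1d(np.arange(12), te)
                lm = LinearRegression().fit(X[np.ix_(tr, cols)], y[tr])
                press += np.sum((lm.predict(X[np.ix_(te, cols)]) -
                                 y[te]) ** 2)
            return float(np.sqrt(press / 12))

        best = None
        for start in range(5):
            chain = oracle_chain(start, 3)
            traj = np.array([oracle_rmse(chain[:s])
                             for s in range(1, len(chain) + 1)])
            size = spa_plateau_size(traj, SPA_PLATEAU_REL, SPA_PLATEAU_ABS)
            key = (traj[size - 1], size, start)
            if best is None or key < best[0]:
                best = (key, sorted(chain[:size]))
        res = spa_select(X, y, grid, max_size=3, n_folds=n_folds)
        assert res.selected_idx.tolist() == best[1]
        assert abs(res.trajectory[res.argmin - 1] - best[0][0]) < 1e-12

    def test_noiseless_mixture_reaches_zero_error(self, grid,
                                                  noiseless_config):
        """With no noise the target is exactly linear in a few bands; the
        RMSE trajectory hits numerical zero by size 3 and growth stops."""
        spectra, reference, _ = simulate_samples(noiseless_config, grid)
        res = spa_select(spectra.to_numpy(), reference["SSC"].to_numpy(),
                         grid, max_size=6, n_folds=4)
        assert res.argmin <= 3
        assert res.trajectory[res.argmin - 1] < 1e-6


class TestPublishedWavelengths:
    def test_firmness_cars_list(self):
        nm = load_published_wavelengths("firmness", "CARS")
        assert len(nm) == 18
        assert nm[:4].tolist() == [397, 402, 421, 432]

    def test_counts_and_proportions(self):
        cars_counts = {ix: len(PUBLISHED_WAVELENGTHS[ix]["CARS"])
                       for ix in ks.INDEX_NAMES}
        assert list(cars_counts.values()) == [32, 18, 26, 29, 32]
        spa_counts = [len(PUBLISHED_WAVELENGTHS[ix]["SPA"])
                      for ix in ks.INDEX_NAMES]
        assert spa_counts == [10, 8, 13, 9, 14]
        assert wavelength_proportion_pct(10) == 3.91
        assert wavelength_proportion_pct(32) == 12.50

    def test_unknown_index_or_method_rejected(self):
        with pytest.raises(ValueError, match="unknown index"):
            load_published_wavelengths("sugar", "CARS")
        with pytest.raises(ValueError, match="unknown method"):
            load_published_wavelengths("SSC", "UVE")

    def test_grid_without_band_rejected(self):
        sparse = WavelengthGrid(np.linspace(390, 1030, 20))
        with pytest.raises(ValueError, match="no band within"):
            load_published_wavelengths("SSC", "CARS", grid=sparse)
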