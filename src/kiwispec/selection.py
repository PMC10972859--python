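"""Feature-wavelength selection: CARS and SPA.

CARS (competitive adaptive reweighted sampling) runs a fixed number of
Monte Carlo rounds.  Each round fits a PLSR on a random subset of the
calibration samples restricted to the currently retained wavelengths,
ranks wavelengths by the absolute PLS regression coefficient |b|, shrinks
the retained count along an exponentially decreasing schedule (all bands
at round 1 down to two at the last round), realizes the new retained set
by adaptive reweighted sampling (weighted draws proportional to |b|,
with replacement, deduplicated), and records the k-fold RMSECV of a PLSR
on that set.  The set from the round with minimum RMSECV wins.

SPA (successive projections algorithm) is deterministic forward
selection of minimally collinear wavelengths: starting from each
candidate band, it repeatedly adds the band whose column has the largest
norm after orthogonal projection onto the complement of the span of the
already-selected columns; chains of growing size are scored by
cross-validated MLR RMSE and growth stops once the relative improvement
falls below a plateau tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import WavelengthGrid
from .models import plsr_coefficients, _cv_rmse_pls

log = logging.getLogger(__name__)

#: SPA plateau rule: stop growing when relative RMSE improvement drops
#: below this, or the RMSE is already numerically zero
SPA_PLATEAU_REL = 0.01
SPA_PLATEAU_ABS = 1e-10


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one wavelength-selection procedure."""

    method: str                      # "CARS" | "SPA"
    selected_idx: np.ndarray         # unique, sorted band indices
    selected_nm: np.ndarray
    trajectory: np.ndarray           # RMSECV per run (CARS) / RMSE per size (SPA)
    argmin: int                      # best run (1-based, CARS) / best size (SPA)
    retained_counts: np.ndarray | None = None   # CARS: wavelengths per run
    seed: int | None = None          # CARS only; SPA is deterministic

    @property
    def n_selected(self) -> int:
        return int(self.selected_idx.size)


def edf_counts(n_bands: int, n_runs: int) -> np.ndarray:
    """Retained-wavelength schedule r_i = a e^(-k i), r_1 = 1, r_N = 2/B.

    Returns the integer retained count per run; round 1 keeps every band,
    the final round keeps two, and the sequence is non-increasing.
    """
    if n_runs < 2:
        raise ValueError("need at least two sampling runs")
    i = np.arange(1, n_runs + 1, dtype=float)
    k = np.log(n_bands / 2.0) / (n_runs - 1)
    a = np.exp(k)                        # so that a·e^(-k·1) = 1
    ratio = a * np.exp(-k * i)
    counts = np.maximum(np.round(ratio * n_bands).astype(int), 2)
    counts[0] = n_bands
    return np.minimum.accumulate(counts)


def _choose_lv(X: np.ndarray, y: np.ndarray, n_folds: int,
               max_lv: int = 10) -> int:
    n, m = X.shape
    cap = int(min(max_lv, m, np.linalg.matrix_rank(X - X.mean(axis=0)),
                  n - int(np.ceil(n / n_folds)) - 1))
    cap = max(cap, 1)
    if cap == 1:
        return 1
    rmse = [_cv_rmse_pls(X, y, lv, n_folds) for lv in range(1, cap + 1)]
    return 1 + int(np.argmin(rmse))


def cars_select(X: np.ndarray, y: np.ndarray, grid: WavelengthGrid,
                n_runs: int = 50, n_folds: int = 5, seed: int = 0,
                mc_ratio: float = 0.8, max_lv: int = 10,
                max_selected: int | None = None) -> SelectionResult:
    """CARS wavelength selection on SNV calibration spectra.

    ``X`` is n x B (SNV, full grid), ``y`` one index.  ``n_runs`` Monte
    Carlo rounds with ``n_folds``-fold RMSECV; each round subsamples
    ``mc_ratio`` of the calibration set.  ``max_selected`` excludes runs
    retaining more wavelengths than a downstream regression can support
    from the winner choice (their RMSECV still appears in the
    trajectory).  Deterministic given (data, seed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if B != len(grid):
        raise ValueError("X does not lie on the stated grid")
    if n < 2 * n_folds:
        raise ValueError(f"need >= {2 * n_folds} calibration samples")
    rng = np.random.default_rng(seed)

    counts = edf_counts(B, n_runs)
    retained = np.arange(B)
    n_sub = max(2 * n_folds, int(round(mc_ratio * n)))
    rmsecv = np.full(n_runs, np.nan)
    kept_counts = np.zeros(n_runs, dtype=int)
    runs: list[np.ndarray] = []

    for run in range(n_runs):
        sub = rng.choice(n, size=n_sub, replace=False)
        Xs = X[np.ix_(sub, retained)]
        lv = _choose_lv(Xs, y[sub], n_folds, max_lv)
        _, coef = plsr_coefficients(Xs, y[sub], lv)
        w = np.abs(coef)

        n_keep = min(int(counts[run]), retained.size)
        top = retained[np.argsort(w)[::-1][:n_keep]]
        w_top = w[np.argsort(w)[::-1][:n_keep]]
        # adaptive reweighted sampling: B weighted draws with replacement,
        # then deduplicate (a variable survives if drawn at least once)
        if w_top.sum() <= 0:
            new = np.sort(top)
        else:
            draws = rng.choice(top, size=B, replace=True,
                               p=w_top / w_top.sum())
            new = np.unique(draws)
        if new.size < 2:
            log.warning("cars_select: fewer than 2 wavelengths retained at "
                        "run %d; trajectory truncated", run + 1)
            rmsecv = rmsecv[:run]
            kept_counts = kept_counts[:run]
            break
        retained = new
        kept_counts[run] = retained.size
        runs.append(retained.copy())

        Xr = X[:, retained]
        lv_r = _choose_lv(Xr, y, n_folds, max_lv)
        val = _cv_rmse_pls(Xr, y, lv_r, n_folds)
        rmsecv[run] = val if np.isfinite(val) else np.nan

    score = rmsecv.copy()
    if max_selected is not None:
        score[kept_counts[:score.size] > max_selected] = np.nan
    if not np.any(np.isfinite(score)):
        raise RuntimeError("cars_select: no eligible run produced a finite "
                           "RMSECV")
    best = int(np.nanargmin(score))
    sel = np.sort(runs[best])
    return SelectionResult(method="CARS", selected_idx=sel,
                           selected_nm=grid.wavelengths[sel],
                           trajectory=rmsecv, argmin=best + 1,
                           retained_counts=kept_counts, seed=seed)


# ---------------------------------------------------------------------------
# SPA

def spa_chain(X: np.ndarray, start: int, max_size: int) -> np.ndarray:
    """Projection chain from one start column.

    Repeatedly appends the column with the largest norm after orthogonal
    projection onto the complement of the selected columns' span.  The
    chain truncates early if every projected norm vanishes (collinear
    remainder).
    """
    X = np.asarray(X, dtype=float)
    n, B = X.shape
    norm0 = np.linalg.norm(X, axis=0)
    scale = norm0.max()
    chain = [start]
    q = X[:, start] / np.linalg.norm(X[:, start])
    Q = q[:, None]
    R = X - Q @ (Q.T @ X)                     # residuals after projection
    while len(chain) < max_size:
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-10 * scale:
            break                              # nothing independent left
        chain.append(nxt)
        q = R[:, nxt] / np.linalg.norm(R[:, nxt])
        Q = np.column_stack([Q, q])
        R = R - q[:, None] * (q @ R)
    return np.array(chain, dtype=int)


def _cv_rmse_mlr(X: np.ndarray, y: np.ndarray, n_folds: int) -> float:
    """k-fold CV RMSE of an intercept+OLS model (unshuffled folds)."""
    n = len(y)
    idx = np.arange(n)
    folds = np.array_split(idx, n_folds)
    press = 0.0
    for te in folds:
        tr = np.setdiff1d(idx, te)
        A = np.column_stack([np.ones(tr.size), X[tr]])
        beta, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        At = np.column_stack([np.ones(te.size), X[te]])
        press += float(np.sum((At @ beta - y[te]) ** 2))
    return float(np.sqrt(press / n))


def spa_plateau_size(rmse_by_size: np.ndarray,
                     rel_tol: float = SPA_PLATEAU_REL,
                     abs_tol: float = SPA_PLATEAU_ABS) -> int:
    """Size at which chain growth stops: grow while the next wavelength
    improves RMSE by at least ``rel_tol`` (relative) and the error is not
    already numerically zero."""
    size = 1
    while size < len(rmse_by_size):
        cur, nxt = rmse_by_size[size - 1], rmse_by_size[size]
        if cur <= abs_tol:
            break
        if (cur - nxt) / cur < rel_tol:
            break
        size += 1
    return size


def spa_select(X: np.ndarray, y: np.ndarray, grid: WavelengthGrid,
               max_size: int = 30, n_folds: int = 5) -> SelectionResult:
    """SPA wavelength selection on SNV calibration spectra.

    Builds a projection chain from every candidate start band, scores
    each chain prefix by ``n_folds``-fold cross-validated MLR RMSE,
    applies the plateau rule per chain, and returns the winning
    (chain, size).  Fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, B = X.shape
    if B != len(grid):
        raise ValueError("X does not lie on the stated grid")
    train = n - int(np.ceil(n / n_folds))
    cap = min(max_size, train - 2, B)
    if cap < 1:
        raise ValueError("too few samples for the requested selection size")

    best = None    # (rmse, size, start, chain, traj)
    for start in range(B):
        chain = spa_chain(X, start, cap)
        traj = np.array([_cv_rmse_mlr(X[:, chain[:s]], y, n_folds)
                         for s in range(1, len(chain) + 1)])
        size = spa_plateau_size(traj)
        key = (traj[size - 1], size, start)
        if best is None or key < best[0]:
            best = (key, chain, traj)
    (score, size, start), chain, traj = best
    sel = np.sort(chain[:size])
    return SelectionResult(method="SPA", selected_idx=sel,
                           selected_nm=grid.wavelengths[sel],
                           trajectory=traj, argmin=size)
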