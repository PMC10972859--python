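"""SPXY calibration/prediction partitioning.

SPXY extends Kennard-Stone sample selection to a joint x-y distance:

    d(i, j) = d_x(i, j) / max d_x  +  d_y(i, j) / max d_y

with Euclidean d_x on the (SNV-preprocessed) spectra and Euclidean d_y
on the autoscaled reference indices.  Selection is max-min: seed with
the pair attaining the maximum joint distance, then repeatedly add the
sample whose minimum distance to the already-selected set is largest.
The first ``n_cal`` selected samples form the calibration set; the rest
form the prediction set.  The procedure is fully deterministic; ties
break toward the smallest original sample position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import snv_rows


@dataclass(frozen=True)
class SplitResult:
    calibration_ids: tuple
    prediction_ids: tuple
    selection_order: tuple          # all ids in max-min selection order

    @property
    def n_cal(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_pred(self) -> int:
        return len(self.prediction_ids)


def _pairwise_euclidean(a: np.ndarray) -> np.ndarray:
    sq = np.sum(a * a, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (a @ a.T)
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


def joint_distance_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Normalized joint x-y distance matrix used by SPXY."""
    dx = _pairwise_euclidean(np.asarray(X, dtype=float))
    dy = _pairwise_euclidean(np.asarray(Y, dtype=float))
    if dx.max() == 0 or dy.max() == 0:
        raise ValueError("degenerate data: all-zero x or y distances")
    return dx / dx.max() + dy / dy.max()


def maxmin_order(d: np.ndarray) -> list[int]:
    """Kennard-Stone max-min selection order over a full distance matrix."""
    n = d.shape[0]
    i, j = np.unravel_index(np.argmax(d), d.shape)
    first = [min(i, j), max(i, j)]
    selected = list(first)
    min_d = np.minimum(d[first[0]], d[first[1]])
    min_d[selected] = -np.inf
    for _ in range(n - 2):
        nxt = int(np.argmax(min_d))        # argmax takes the lowest index on ties
        selected.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
        min_d[nxt] = -np.inf
    return selected


def spxy_split(spectra: pd.DataFrame, reference: pd.DataFrame,
               n_cal: int, snv_x: bool = True) -> SplitResult:
    """Partition row-aligned spectra/reference tables into cal/pred sets.

    Distances are computed on SNV spectra (``snv_x=True``) and on
    per-index autoscaled reference values, all five indices jointly.
    """
    if list(spectra.index) != list(reference.index):
        raise ValueError("spectra and reference tables are not row-aligned")
    n = len(spectra)
    if not (2 <= n_cal < n):
        raise ValueError(f"n_cal must be in [2, {n}); got {n_cal}")

    X = spectra.to_numpy(dtype=float)
    if snv_x:
        X = snv_rows(X)
    Y = reference.to_numpy(dtype=float)
    sd = Y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("degenerate data: a reference index has zero variance")
    Y = (Y - Y.mean(axis=0)) / sd

    order = maxmin_order(joint_distance_matrix(X, Y))
    ids = list(spectra.index)
    cal = [ids[k] for k in order[:n_cal]]
    pred = [i for i in ids if i not in set(cal)]     # original order
    return SplitResult(calibration_ids=tuple(cal), prediction_ids=tuple(pred),
                       selection_order=tuple(ids[k] for k in order))


def summarize_split(split: SplitResult, reference: pd.DataFrame,
                    decimals: int = 2) -> pd.DataFrame:
    """Per-set, per-index min / max / mean +/- sd summary table.

    Mirrors the standard partition-statistics report: one row per
    (set, index), sample standard deviation, values rounded half-up to
    ``decimals``.  Sets of size < 2 get an undefined-sd marker.
    """
    from .evaluation import round_half_up

    rows = []
    for set_name, ids in (("calibration", split.calibration_ids),
                          ("prediction", split.prediction_ids)):
        sub = reference.loc[list(ids)]
        for col in reference.columns:
            v = sub[col].to_numpy(dtype=float)
            sd = v.std(ddof=1) if len(v) >= 2 else np.nan
            rows.append({
                "set": set_name, "n": len(v), "index": col,
                "min": round_half_up(v.min(), decimals),
                "max": round_half_up(v.max(), decimals),
                "mean": round_half_up(v.mean(), decimals),
                "sd": round_half_up(sd, decimals) if np.isfinite(sd) else "n/a",
            })
    return pd.DataFrame(rows)
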