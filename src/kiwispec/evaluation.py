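"""Model performance metrics: R2, RMSE, RPD, and comparison tables.

For a calibration set of size n_C and a prediction set of size n_P:

    R2   = 1 - sum (y_act - y_hat)^2 / sum (y_act - y_mean)^2
    RMSE = sqrt( (1/n) sum (y_act - y_hat)^2 )
    RPD  = SD / RMSEP

where y_mean is the evaluated set's own reference mean and SD is the
sample standard deviation (n-1) of the prediction-set reference values.
RPD quality bands: < 1.4 below-poor, [1.4, 1.8) poor, [1.8, 2.0) good,
>= 2.0 excellent.  Displayed values are rounded half-up to 2 decimals;
raw doubles are kept internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (2.8991 -> 2.90 at 2 dp), unlike banker's."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rmse(y_act: np.ndarray, y_hat: np.ndarray) -> float:
    y_act = np.asarray(y_act, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    return float(np.sqrt(np.mean((y_act - y_hat) ** 2)))


def r_squared(y_act: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - SSres/SStot around the evaluated set's own mean (may be < 0)."""
    y_act = np.asarray(y_act, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    sstot = float(np.sum((y_act - y_act.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("R^2 undefined: reference values have zero variance")
    return 1.0 - float(np.sum((y_act - y_hat) ** 2)) / sstot


def rpd(sd: float, rmsep: float) -> float:
    """Residual predictive deviation SD / RMSEP (inf marker when RMSEP=0)."""
    if sd < 0:
        raise ValueError("SD must be non-negative")
    if rmsep == 0.0:
        return math.inf
    return sd / rmsep


def rpd_band(value: float) -> str:
    """Quality band of an RPD value."""
    if not math.isfinite(value) or value <= 0:
        if value == math.inf:
            return "excellent"
        raise ValueError("RPD must be a positive finite number")
    if value < 1.4:
        return "below-poor"
    if value < 1.8:
        return "poor"
    if value < 2.0:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class EvaluationReport:
    """Calibration/prediction performance of one model on one index."""

    model_name: str
    index: str
    units: str
    r2_cal: float
    rmse_cal: float
    r2_pred: float
    rmse_pred: float
    rpd: float
    band: str
    n_cal: int
    n_pred: int


def evaluate(y_cal_act, y_cal_hat, y_pred_act, y_pred_hat,
             model_name: str = "", index: str = "",
             units: str = "") -> EvaluationReport:
    """Score one calibrated model on its calibration and prediction sets."""
    y_pred_act = np.asarray(y_pred_act, float).ravel()
    if len(np.atleast_1d(y_cal_act)) == 0 or y_pred_act.size == 0:
        raise ValueError("both sample sets must be non-empty")
    if y_pred_act.size < 2:
        raise ValueError("prediction set needs >= 2 samples (SD undefined)")
    rmsec = rmse(y_cal_act, y_cal_hat)
    rmsep = rmse(y_pred_act, y_pred_hat)
    sd = float(np.std(y_pred_act, ddof=1))
    value = rpd(sd, rmsep)
    return EvaluationReport(
        model_name=model_name, index=index, units=units,
        r2_cal=r_squared(y_cal_act, y_cal_hat), rmse_cal=rmsec,
        r2_pred=r_squared(y_pred_act, y_pred_hat), rmse_pred=rmsep,
        rpd=value, band=rpd_band(value),
        n_cal=len(np.atleast_1d(y_cal_act)), n_pred=int(y_pred_act.size))


def report_table(reports) -> pd.DataFrame:
    """Model-comparison table: rows model x index, 2-dp half-up display.

    Column order follows the conventional calibration/prediction layout:
    R2C, RMSEC, R2P, RMSEP, RPD.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no evaluation reports to tabulate")
    rows = []
    for r in reports:
        rows.append({
            "model": r.model_name, "index": r.index,
            "R2C": round_half_up(r.r2_cal), "RMSEC": round_half_up(r.rmse_cal),
            "R2P": round_half_up(r.r2_pred), "RMSEP": round_half_up(r.rmse_pred),
            "RPD": round_half_up(r.rpd), "band": r.band,
        })
    return pd.DataFrame(rows)
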