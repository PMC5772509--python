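"""Scoring fractionation models against adjusted proxy records.

Each candidate model yields a predicted δ¹³Cₚ curve through time; a
record compilation (geography-adjusted, converted to plant-equivalent
values) yields residuals record − curve at the record ages (linear
interpolation between grid points; out-of-span records are skipped with
a log entry).  Models are compared on

* RMSE  = √(Σr²/n);
* AIC   = 2k − 2lnL;
* BIC   = ln(n)·k − 2lnL,

with L the maximised Gaussian likelihood of the residuals.  The error
model is zero-mean Gaussian with variance at its MLE σ̂² = Σr²/n (the
model curve, not the sample mean, plays the role of the mean); a
fixed-σ variant is available.  The constants of each model are fixed by
calibration, not refitted, so k counts the calibrated constants:
3 for the constant-setpoint and hyperbolic models (a, b, ratio and
A, B, C) and 4 for the linear-setpoint models (a, b, slope, intercept).
These are conventions, configurable and always reported with the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .icecore_curves import SplineCurve

__all__ = [
    "DEFAULT_K",
    "FitScore",
    "residuals",
    "rmse",
    "log_likelihood",
    "information_criteria",
    "score_model",
    "score_models",
]

logger = logging.getLogger(__name__)

#: Calibrated-constant counts per registry model key.
DEFAULT_K: dict[str, int] = {
    "farquhar1982": 3,
    "voelker2016g": 4,
    "voelker2016a": 4,
    "sj2012": 3,
}


@dataclass(frozen=True)
class FitScore:
    """Goodness-of-fit summary for one model against one record set."""

    model: str
    n: int
    k: int
    rmse: float
    loglik: float
    aic: float
    bic: float


def residuals(
    curve: SplineCurve,
    records: pd.DataFrame,
    value_col: str = "d13c_plant_adj",
    age_col: str = "age_kyr_bp",
) -> np.ndarray:
    """Record-minus-curve residuals (‰) at the record ages.

    Records whose age falls outside the curve span are skipped (logged),
    matching the no-extrapolation rule for the curves.
    """
    ages = records[age_col].to_numpy(dtype=float)
    vals = records[value_col].to_numpy(dtype=float)
    ok = (ages >= curve.grid[0]) & (ages <= curve.grid[-1])
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("skipped %d records outside the curve span", n_skip)
    if not ok.any():
        raise ValueError("no records fall within the curve span")
    return vals[ok] - np.interp(ages[ok], curve.grid, curve.mean)


def rmse(res) -> float:
    """Root mean square of the residuals (‰)."""
    r = np.asarray(res, dtype=float)
    if r.size == 0:
        raise ValueError("no residuals")
    return float(np.sqrt(np.mean(r * r)))


def log_likelihood(res, sigma: float | None = None) -> float:
    """Gaussian log-likelihood of residuals about zero.

    With ``sigma=None`` the variance is profiled out at its MLE
    σ̂² = Σr²/n, giving lnL = −n/2·(ln(2πσ̂²) + 1).
    """
    r = np.asarray(res, dtype=float)
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 residuals")
    ss = float(np.sum(r * r))
    if sigma is None:
        s2 = ss / n
        if s2 <= 0:
            raise ValueError("zero residual variance: likelihood degenerate")
        return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return -0.5 * n * np.log(2.0 * np.pi * sigma**2) - ss / (2.0 * sigma**2)


def information_criteria(
    res, k: int, sigma: float | None = None
) -> tuple[float, float]:
    """(AIC, BIC) of a k-parameter model from its residuals."""
    r = np.asarray(res, dtype=float)
    ll = log_likelihood(r, sigma=sigma)
    aic = 2.0 * k - 2.0 * ll
    bic = np.log(r.size) * k - 2.0 * ll
    return float(aic), float(bic)


def score_model(
    name: str,
    curve: SplineCurve,
    records: pd.DataFrame,
    k: int,
    value_col: str = "d13c_plant_adj",
) -> FitScore:
    """Full score of one model curve against a record table."""
    r = residuals(curve, records, value_col=value_col)
    aic, bic = information_criteria(r, k)
    return FitScore(
        model=name,
        n=int(r.size),
        k=int(k),
        rmse=rmse(r),
        loglik=log_likelihood(r),
        aic=aic,
        bic=bic,
    )


def score_models(
    curves: dict[str, SplineCurve],
    records: pd.DataFrame,
    k: dict[str, int] | None = None,
    value_col: str = "d13c_plant_adj",
) -> pd.DataFrame:
    """Score several model curves; returns a frame sorted by BIC."""
    k = dict(DEFAULT_K) if k is None else k
    rows = [
        score_model(name, curve, records, k[name], value_col=value_col)
        for name, curve in curves.items()
    ]
    out = pd.DataFrame([vars(s) for s in rows]).set_index("model")
    return out.sort_values("bic")
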