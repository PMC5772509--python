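"""Continuous atmospheric histories from irregular ice-core samples.

Ice-core measurements of CO₂ concentration and δ¹³C_CO₂ are irregular in
age and carry per-sample 1σ errors.  A Monte Carlo average (MCA)
smoothing spline turns them into continuous curves with uncertainty: in
each of ``n_rep`` replicates every sample value is perturbed by a draw
from its error distribution and a cubic smoothing spline is fitted; the
curve mean and 1σ are the per-grid-point statistics over replicates.

The smoothing strength is set by a *cutoff period*: the spline's
roughness penalty λ is chosen so that, for the record's average sampling
density, the equivalent low-pass filter has 50% amplitude response at
the cutoff (the standard convention for smoothing-spline CO₂ records;
375 yr for the pre-industrial compilation).  Formally, a cubic smoothing
spline minimising Σ(yᵢ−f(xᵢ))² + λ∫f″² behaves in the continuum limit as
a filter with response 1/(1 + (λ/ρ)ω⁴), ρ the number of points per unit
age, giving λ = ρ·(T_c/2π)⁴.

Curves are evaluated on a regular age grid (default 0.1 kyr step) strictly
inside the data span — no extrapolation.  The anthropogenic era, where
sampling is dense and the signal steep, is splined *without* a cutoff and
merged onto the pre-industrial curve with a one-grid-step cross-fade.

Model δ¹³Cₚ curves are produced by pushing the pCO₂ and δ¹³C_CO₂ curves
through a fractionation model, with Monte Carlo uncertainty propagation,
and episodes of rapid predicted change are located by thresholding the
local rate of change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .fractionation_models import AtmosState, ModelSpec, predict_delta_p

__all__ = [
    "SplineCurve",
    "Episode",
    "cutoff_lambda",
    "mca_spline",
    "merge_anthropogenic",
    "model_curve",
    "expanded_uncertainty",
    "detect_episodes",
    "MODERN_PLANT_SPREAD",
]

#: 1σ spread of the modern global C3 plant δ¹³C data set (‰), combined in
#: quadrature with propagated curve uncertainty to give conservative
#: "expanded" bounds on model δ¹³Cₚ curves.
MODERN_PLANT_SPREAD = 1.62

DEFAULT_GRID_STEP_KYR = 0.1


@dataclass
class SplineCurve:
    """A curve on a regular age grid with pointwise 1σ uncertainty.

    ``grid`` is strictly increasing in age (kyr BP, so young → old);
    ``meta`` records provenance (seed, replicate count, cutoff, ...).
    """

    grid: np.ndarray
    mean: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.grid.shape == self.mean.shape == self.sigma.shape):
            raise ValueError("grid, mean, sigma must share a shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing in age")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def interp(self, ages) -> np.ndarray:
        """Linear interpolation of the curve mean at ``ages`` (in-span)."""
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < self.grid[0]) or np.any(ages > self.grid[-1]):
            raise ValueError("requested ages outside the curve span")
        return np.interp(ages, self.grid, self.mean)


@dataclass(frozen=True)
class Episode:
    """A contiguous interval of rapid change (ages in kyr BP, older first)."""

    start: float  # older bound
    end: float    # younger bound
    amplitude: float
    mean_rate: float

    def __post_init__(self) -> None:
        if not self.start > self.end:
            raise ValueError("start (older) must exceed end (younger)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def duration(self) -> float:
        return self.start - self.end


def cutoff_lambda(n_points: int, span_kyr: float, cutoff_kyr: float) -> float:
    """Roughness penalty λ giving 50% attenuation at the cutoff period."""
    if cutoff_kyr <= 0 or span_kyr <= 0 or n_points < 2:
        raise ValueError("invalid cutoff/span/point count")
    density = n_points / span_kyr
    return density * (cutoff_kyr / (2.0 * np.pi)) ** 4


def _clean_samples(samples: pd.DataFrame) -> pd.DataFrame:
    s = samples
    if "outlier" in s:
        s = s[~s["outlier"].astype(bool)]
    s = s[np.isfinite(s["age_kyr_bp"]) & np.isfinite(s["value"])]
    if np.any(s["sigma"].to_numpy() < 0):
        raise ValueError("sample sigma must be non-negative")
    return s.sort_values("age_kyr_bp")


def _collapse_duplicates(x: np.ndarray, y: np.ndarray):
    """Average values at exactly-duplicated ages (multi-core compilations)."""
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size == x.size:
        return x, y
    sums = np.bincount(inv, weights=y)
    counts = np.bincount(inv)
    return ux, sums / counts


def _default_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = max(int(round((hi - lo) / step)), 1) + 1
    return np.linspace(lo, hi, n)


def mca_spline(
    samples: pd.DataFrame,
    n_rep: int = 1000,
    cutoff_kyr: float | None = 0.375,
    grid: np.ndarray | None = None,
    grid_step_kyr: float = DEFAULT_GRID_STEP_KYR,
    *,
    seed: int,
    uniform: bool = False,
    lam: float | None = None,
) -> SplineCurve:
    """Monte Carlo average smoothing spline of an irregular noisy series.

    Parameters
    ----------
    samples
        DataFrame with columns ``age_kyr_bp, value, sigma`` and optional
        ``outlier`` (flagged rows are excluded before fitting) and
        ``core``.
    n_rep
        Number of replicate fits (1000 in the reference configuration).
    cutoff_kyr
        Cutoff period in kyr (0.375 = 375 yr); ``None`` lets the spline
        choose its smoothing by generalised cross-validation.
    grid
        Evaluation ages; defaults to a regular ``grid_step_kyr`` grid
        over the data span.  Must lie inside the span (no extrapolation).
    seed
        Mandatory RNG seed, recorded in the output metadata.
    uniform
        Perturb with Uniform(−σ, σ) instead of Gaussian(0, σ).
    lam
        Explicit roughness penalty, overriding the cutoff mapping.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    s = _clean_samples(samples)
    if len(s) < 4:
        raise ValueError("need at least 4 usable (non-outlier) samples")
    x = s["age_kyr_bp"].to_numpy(dtype=float)
    val = s["value"].to_numpy(dtype=float)
    sig = s["sigma"].to_numpy(dtype=float)

    lo, hi = x.min(), x.max()
    if grid is None:
        grid = _default_grid(lo, hi, grid_step_kyr)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
            raise ValueError("grid extends beyond the data span")

    if lam is None and cutoff_kyr is not None:
        lam = cutoff_lambda(len(s), hi - lo, cutoff_kyr)

    rng = np.random.default_rng(seed)
    reps = np.empty((n_rep, grid.size))
    for i in range(n_rep):
        if uniform:
            pert = rng.uniform(-sig, sig)
        else:
            pert = rng.normal(0.0, 1.0, size=sig.size) * sig
        xi, yi = _collapse_duplicates(x, val + pert)
        spl = make_smoothing_spline(xi, yi, lam=lam)
        reps[i] = spl(grid)
    mean = reps.mean(axis=0)
    sigma = reps.std(axis=0, ddof=1) if n_rep > 1 else np.zeros_like(mean)
    return SplineCurve(
        grid=grid,
        mean=mean,
        sigma=sigma,
        meta={
            "seed": seed,
            "n_rep": n_rep,
            "cutoff_kyr": cutoff_kyr,
            "lam": lam,
            "perturbation": "uniform" if uniform else "gaussian",
            "n_samples": int(len(s)),
        },
    )


def merge_anthropogenic(
    pre_industrial: SplineCurve, modern_samples: pd.DataFrame
) -> SplineCurve:
    """Extend a pre-industrial curve with a no-cutoff modern segment.

    The modern samples (dense, precise, steep anthropogenic signal) are
    fitted with an interpolating cubic spline — no cutoff attenuation —
    and the combined curve prefers the modern segment from the oldest
    modern sample toward the present, with a linear cross-fade over one
    grid step where both segments exist.  A gap between the modern span
    and the pre-industrial grid larger than one grid step is an error.
    """
    if modern_samples is None or len(modern_samples) == 0:
        return pre_industrial
    s = _clean_samples(modern_samples)
    x = s["age_kyr_bp"].to_numpy(dtype=float)
    y = s["value"].to_numpy(dtype=float)
    sig = s["sigma"].to_numpy(dtype=float)
    x, y = _collapse_duplicates(x, y)

    pre = pre_industrial
    step = pre.step
    if x.max() < pre.grid[0] - step:
        raise ValueError(
            "gap between modern samples and pre-industrial curve exceeds "
            "one grid step"
        )
    cs = CubicSpline(x, y)

    # grid extension younger than the pre-industrial start, same step
    n_ext = int(np.ceil((pre.grid[0] - x.min()) / step - 1e-9))
    ext = pre.grid[0] - step * np.arange(n_ext, 0, -1) if n_ext > 0 else np.empty(0)
    ext = ext[ext >= x.min() - 1e-9]  # stay inside the modern data span
    grid = np.concatenate([ext, pre.grid])

    t_b = x.max()  # junction: oldest modern sample
    modern_ok = (grid >= x.min() - 1e-9) & (grid <= t_b + 1e-9)
    pre_ok = grid >= pre.grid[0] - 1e-9

    mean = np.full(grid.size, np.nan)
    sigma = np.zeros(grid.size)
    pre_mean = np.interp(grid, pre.grid, pre.mean)
    pre_sig = np.interp(grid, pre.grid, pre.sigma)
    mod_mean = cs(grid)
    mod_sig = np.interp(grid, x, np.interp(x, s["age_kyr_bp"], sig))

    # weight on the pre-industrial curve ramps 0 → 1 over the grid step
    # ending at the junction (older side keeps the smoothed curve)
    w_pre = np.clip((grid - (t_b - step)) / step, 0.0, 1.0)
    w_pre[~pre_ok] = 0.0
    w_pre[~modern_ok] = 1.0
    mean = w_pre * np.where(pre_ok, pre_mean, 0.0) + (1 - w_pre) * np.where(
        modern_ok, mod_mean, 0.0
    )
    sigma = w_pre * np.where(pre_ok, pre_sig, 0.0) + (1 - w_pre) * np.where(
        modern_ok, mod_sig, 0.0
    )
    meta = dict(pre.meta)
    meta.update({"merged_modern_n": int(len(s)), "junction_kyr_bp": t_b})
    return SplineCurve(grid=grid, mean=mean, sigma=sigma, meta=meta)


def _matched_draws(rng: np.random.Generator, n_rep: int, npts: int) -> np.ndarray:
    """Standard-normal draws moment-matched per column (mean 0, sd 1).

    Variance-reduction: makes linear propagation exact while leaving
    nonlinear propagation unbiased Monte Carlo.
    """
    z = rng.standard_normal((n_rep, npts))
    z -= z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return z / sd


def model_curve(
    model: ModelSpec,
    pco2: SplineCurve,
    d13c: SplineCurve,
    n_rep: int = 1000,
    *,
    seed: int,
) -> SplineCurve:
    """Predicted δ¹³Cₚ curve with Monte Carlo propagated uncertainty.

    The curve mean is the model applied pointwise to the input curve
    means; the 1σ band comes from ``n_rep`` joint draws of the pCO₂ and
    δ¹³C_CO₂ curves from their independent per-point 1σ.
    """
    if not np.array_equal(pco2.grid, d13c.grid):
        raise ValueError("pco2 and d13c curves must share a grid")
    atmos = AtmosState(pco2=pco2.mean, d13c_co2=d13c.mean)
    mean = np.asarray(predict_delta_p(model, atmos), dtype=float)

    if n_rep < 2 or (np.all(pco2.sigma == 0) and np.all(d13c.sigma == 0)):
        sigma = np.zeros_like(mean)
    else:
        rng = np.random.default_rng(seed)
        npts = pco2.grid.size
        zp = _matched_draws(rng, n_rep, npts)
        zd = _matched_draws(rng, n_rep, npts)
        p_draws = np.clip(pco2.mean + zp * pco2.sigma, 1e-6, None)
        d_draws = d13c.mean + zd * d13c.sigma
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            preds = predict_delta_p(
                model, AtmosState(pco2=p_draws, d13c_co2=d_draws)
            )
        sigma = np.asarray(preds).std(axis=0, ddof=1)
    return SplineCurve(
        grid=pco2.grid.copy(),
        mean=mean,
        sigma=sigma,
        meta={"model": model.name, "seed": seed, "n_rep": n_rep},
    )


def expanded_uncertainty(curve_sigma, modern_spread: float = MODERN_PLANT_SPREAD):
    """Quadrature of propagated curve σ with the modern plant 1σ spread.

    Gives conservative bounds representing the plausible range of actual
    C3 plant values around a model curve, not just analytical error.
    """
    cs = np.asarray(curve_sigma, dtype=float)
    if np.any(cs < 0) or modern_spread < 0:
        raise ValueError("uncertainties must be non-negative")
    out = np.sqrt(modern_spread**2 + cs**2)
    return out if out.ndim else float(out)


def detect_episodes(
    curve: SplineCurve,
    amp_min: float = 1.0,
    rate_min: float = 0.25,
    exclude_after: float | None = None,
    rate_baseline_kyr: float | None = None,
) -> list[Episode]:
    """Locate maximal intervals of rapid, high-amplitude change.

    The local rate (‰/kyr) is the centred finite difference of the curve
    mean on its grid (one-sided at the endpoints).  Maximal contiguous
    runs with \\|rate\\| ≥ ``rate_min`` are kept when the total change
    across the run reaches ``amp_min``; episodes lying entirely younger
    than ``exclude_after`` (kyr BP) — e.g. the anthropogenic era — are
    dropped.  Episodes are returned oldest first.

    On curves carrying residual measurement noise, grid-step differences
    are dominated by that noise; ``rate_baseline_kyr`` widens the
    centred difference to span ±baseline/2 around each grid point, which
    stabilises the rate without re-smoothing the curve.
    """
    if rate_baseline_kyr is None:
        rate = np.gradient(curve.mean, curve.grid)
    else:
        h = rate_baseline_kyr / 2.0
        hi = np.clip(
            np.searchsorted(curve.grid, curve.grid + h, side="left"),
            0, curve.grid.size - 1,
        )
        lo = np.clip(
            np.searchsorted(curve.grid, curve.grid - h, side="right") - 1,
            0, curve.grid.size - 1,
        )
        rate = (curve.mean[hi] - curve.mean[lo]) / (
            curve.grid[hi] - curve.grid[lo]
        )
    mask = np.abs(rate) >= rate_min
    episodes: list[Episode] = []
    i = 0
    n = mask.size
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        if j > i:
            amp = abs(curve.mean[j] - curve.mean[i])
            start, end = curve.grid[j], curve.grid[i]  # older, younger
            if amp >= amp_min and not (
                exclude_after is not None and start < exclude_after
            ):
                episodes.append(
                    Episode(
                        start=float(start),
                        end=float(end),
                        amplitude=float(amp),
                        mean_rate=float(amp / (start - end)),
                    )
                )
        i = j + 1
    episodes.sort(key=lambda e: e.start, reverse=True)
    return episodes
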