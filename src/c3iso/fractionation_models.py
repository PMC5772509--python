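"""Forward models of carbon isotope fractionation in C3 land plants.

Four models predict the stable carbon isotope composition of C3 plant
tissue (δ¹³Cₚ, ‰ VPDB) from the state of the atmosphere — its CO₂
concentration (cₐ = pCO₂, ppmv) and isotopic composition (δ¹³C_CO₂, ‰):

* ``Farquhar-1982`` — the classical diffusion/carboxylation expression

      δ¹³Cₚ = δ¹³C_CO₂ − a − (b − a)·(cᵢ/cₐ)

  with a constant leaf gas-exchange setpoint cᵢ/cₐ = 0.6.  Because the
  setpoint is fixed, this model predicts *no* dependence on pCO₂.
* ``Voelker-2016g`` / ``Voelker-2016a`` — the same expression, but with
  cᵢ/cₐ a linear function of cₐ calibrated for gymnosperms
  (0.00038·cₐ + 0.502) and woody angiosperms (0.00031·cₐ + 0.649).
* ``SJ-2012`` — the hyperbolic discrimination model fitted to growth
  chamber and Last Glacial data,

      Δ¹³C = A·B·(pCO₂ + C) / (A + B·(pCO₂ + C)),

  converted to δ¹³Cₚ through the exact discrimination definition
  Δ¹³C = (δ¹³C_CO₂ − δ¹³Cₚ) / (1 + δ¹³Cₚ/1000).

All constants are exposed on the parameter dataclasses and may be
overridden.  The Farquhar family is applied in its linear-in-δ form as
written; SJ-2012 alone goes through the exact Δ ↔ δ inversion.  Extra
terms for mesophyll conductance, photorespiration and dark respiration
are deliberately omitted (assumed negligible over the calibrated range).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "AtmosState",
    "ConstantCiCa",
    "LinearCiCa",
    "FarquharParams",
    "SJParams",
    "ModelSpec",
    "MODELS",
    "MODERN_D13C_CO2",
    "get_model",
    "ci_ca",
    "delta_p_farquhar",
    "discrimination_sj",
    "discrimination_from_deltas",
    "delta_p_from_discrimination",
    "predict_delta_p",
]

#: Modern atmospheric δ¹³C_CO₂ (‰ VPDB) used for present-day anchor checks.
#: This is the value algebraically required for the constant-cᵢ/cₐ model to
#: reproduce the modern global C3 plant mean of −27.1‰; override freely.
MODERN_D13C_CO2 = -8.4

_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class AtmosState:
    """Atmospheric boundary condition for the fractionation models.

    Parameters
    ----------
    pco2 : float or array
        CO₂ partial pressure / concentration, ppmv (cₐ).  Must be > 0.
    d13c_co2 : float or array
        δ¹³C of atmospheric CO₂, ‰ VPDB.  Physically plausible values lie
        in [−20, 0]; values outside trigger a warning but are accepted.
    """

    pco2: Union[float, np.ndarray]
    d13c_co2: Union[float, np.ndarray]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.pco2) <= 0):
            raise ValueError("pco2 must be strictly positive (ppmv)")
        d = np.asarray(self.d13c_co2, dtype=float)
        if np.any(d < -20.0) or np.any(d > 0.0):
            warnings.warn(
                "d13c_co2 outside the physical range [-20, 0] permil",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ConstantCiCa:
    """Constant leaf gas-exchange setpoint: cᵢ/cₐ = ``ratio`` for all cₐ."""

    ratio: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("constant ci/ca ratio must lie in (0, 1)")


@dataclass(frozen=True)
class LinearCiCa:
    """Linear setpoint cᵢ/cₐ = slope·cₐ + intercept, clamped to (0, 1)."""

    slope: float
    intercept: float


@dataclass(frozen=True)
class FarquharParams:
    """Constants of the diffusion/carboxylation model.

    ``a`` is the fractionation during gaseous diffusion of CO₂ through the
    boundary layer and stomata (default 4.4‰, from the reduced masses of
    the isotopologues); ``b`` the net discrimination during carboxylation
    (default 28.2‰, tuned to reproduce the modern global plant mean).
    """

    a: float = 4.4
    b: float = 28.2
    ci_ca: Union[ConstantCiCa, LinearCiCa] = field(
        default_factory=ConstantCiCa
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.a < self.b:
            raise ValueError("require 0 < a < b (permil)")


@dataclass(frozen=True)
class SJParams:
    """Fitted constants of the hyperbolic discrimination model.

    ``A`` (‰) is the high-pCO₂ asymptote of Δ¹³C, ``B`` (‰/ppmv) the
    initial slope scale, ``C`` (ppmv) a concentration offset.
    """

    A: float = 28.26
    B: float = 0.22
    C: float = 23.9

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0 or self.C <= 0:
            raise ValueError("A, B, C must all be strictly positive")


@dataclass(frozen=True)
class ModelSpec:
    """A named fractionation model plus its parameter set."""

    name: str
    params: Union[FarquharParams, SJParams]

    def __post_init__(self) -> None:
        if not isinstance(self.params, (FarquharParams, SJParams)):
            raise TypeError("params must be FarquharParams or SJParams")


#: Registry of the four named models, addressable by short key.
MODELS: dict[str, ModelSpec] = {
    "farquhar1982": ModelSpec(
        "Farquhar-1982", FarquharParams(ci_ca=ConstantCiCa(0.6))
    ),
    "voelker2016g": ModelSpec(
        "Voelker-2016g", FarquharParams(ci_ca=LinearCiCa(0.00038, 0.502))
    ),
    "voelker2016a": ModelSpec(
        "Voelker-2016a", FarquharParams(ci_ca=LinearCiCa(0.00031, 0.649))
    ),
    "sj2012": ModelSpec("SJ-2012", SJParams()),
}

_DISPLAY_TO_KEY = {m.name: k for k, m in MODELS.items()}


def get_model(name: str) -> ModelSpec:
    """Look up a model by registry key (``sj2012``) or display name
    (``SJ-2012``)."""
    key = name if name in MODELS else _DISPLAY_TO_KEY.get(name, "")
    if key not in MODELS:
        raise KeyError(
            f"unknown model {name!r}; choose from {sorted(MODELS)}"
        )
    return MODELS[key]


def ci_ca(params: FarquharParams, ca):
    """Evaluate the cᵢ/cₐ setpoint at atmospheric concentration ``ca`` (ppmv).

    Constant strategies ignore ``ca``.  Linear strategies evaluate
    slope·cₐ + intercept and clamp the result into (0, 1), warning when a
    clamp occurs (the calibrations are never meant to be evaluated there).
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca must be strictly positive (ppmv)")
    strat = params.ci_ca
    if isinstance(strat, ConstantCiCa):
        out = np.broadcast_to(np.float64(strat.ratio), ca.shape).copy()
    else:
        out = strat.slope * ca + strat.intercept
        if np.any(out <= 0.0) or np.any(out >= 1.0):
            warnings.warn(
                "linear ci/ca evaluated outside (0, 1); clamping",
                stacklevel=2,
            )
            out = np.clip(out, _CLAMP_EPS, 1.0 - _CLAMP_EPS)
    return out if out.ndim else float(out)


def delta_p_farquhar(params: FarquharParams, atmos: AtmosState):
    """δ¹³Cₚ (‰) from the diffusion/carboxylation expression."""
    r = ci_ca(params, atmos.pco2)
    out = (
        np.asarray(atmos.d13c_co2, dtype=float)
        - params.a
        - (params.b - params.a) * r
    )
    return out if np.ndim(out) else float(out)


def discrimination_sj(params: SJParams, pco2):
    """Hyperbolic discrimination Δ¹³C (‰) at ``pco2`` (ppmv).

    Strictly increasing in pCO₂ and bounded above by ``A``.
    """
    p = np.asarray(pco2, dtype=float)
    if np.any(p <= 0):
        raise ValueError("pco2 must be strictly positive (ppmv)")
    t = params.B * (p + params.C)
    out = params.A * t / (params.A + t)
    return out if out.ndim else float(out)


def discrimination_from_deltas(d13c_co2, d13c_p):
    """Δ¹³C (‰) from source and plant compositions (exact definition)."""
    d13c_co2 = np.asarray(d13c_co2, dtype=float)
    d13c_p = np.asarray(d13c_p, dtype=float)
    out = (d13c_co2 - d13c_p) / (1.0 + d13c_p / 1000.0)
    return out if out.ndim else float(out)


def delta_p_from_discrimination(d13c_co2, big_delta):
    """Invert the discrimination definition for δ¹³Cₚ (‰).

    Exact algebraic inverse of :func:`discrimination_from_deltas`:
    δ¹³Cₚ = (δ¹³C_CO₂ − Δ) / (1 + Δ/1000).  Singular at Δ = −1000‰.
    """
    bd = np.asarray(big_delta, dtype=float)
    if np.any(bd <= -1000.0):
        raise ValueError("discrimination must exceed -1000 permil")
    out = (np.asarray(d13c_co2, dtype=float) - bd) / (1.0 + bd / 1000.0)
    return out if out.ndim else float(out)


def predict_delta_p(model: ModelSpec, atmos: AtmosState):
    """Dispatch δ¹³Cₚ prediction over the model registry.

    Farquhar-family models evaluate the linear-in-δ expression directly;
    SJ-2012 composes the hyperbolic discrimination with the exact
    Δ → δ¹³Cₚ inversion.
    """
    if isinstance(model.params, FarquharParams):
        return delta_p_farquhar(model.params, atmos)
    big_delta = discrimination_sj(model.params, atmos.pco2)
    return delta_p_from_discrimination(atmos.d13c_co2, big_delta)
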