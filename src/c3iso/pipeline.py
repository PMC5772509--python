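"""End-to-end deglacial decomposition: records + GCM table → pCO₂ effect.

Chains the library stages in the order of the study design: curation
filters → tissue conversion to plant-equivalent values → geographic
adjustment → pre/post window means → GCM-ensemble MAP correction →
residual pCO₂ effect with quadrature uncertainties and the per-100-ppmv
rescaling, plus the one-sided group-shift test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition_stats import (
    CO2_ISOTOPE_TERM,
    DEGLACIAL_RISE_PPMV,
    EffectDecomposition,
    decompose,
    group_shift_test,
    quadrature,
)
from .geo_adjustment import adjust_records
from .map_correction import MapEffect, cohort_map_effect
from .proxy_records import (
    DEFAULT_WINDOWS,
    OffsetConstants,
    filter_records,
    group_means,
    to_plant_equivalent,
)

__all__ = ["DecompositionResult", "deglacial_decomposition"]


@dataclass(frozen=True)
class DecompositionResult:
    """Everything the deglacial contrast produces, in one place."""

    group_means: pd.DataFrame
    map_effect: MapEffect
    decomposition: EffectDecomposition
    t_statistic: float
    p_value: float
    n_records: int


def _window_labels(ages: np.ndarray, windows) -> np.ndarray:
    lab = np.full(ages.shape, "", dtype=object)
    for name, (young, old) in windows.items():
        lab[(ages >= young) & (ages < old)] = name
    return lab


def deglacial_decomposition(
    records: pd.DataFrame,
    gcm_table: pd.DataFrame,
    windows=DEFAULT_WINDOWS,
    rise_ppmv: float = DEGLACIAL_RISE_PPMV,
    d13c_samples: pd.DataFrame | None = None,
    keep_co2_term: bool = False,
    offsets: OffsetConstants = OffsetConstants(),
    min_c3_fraction: float | None = 0.9,
    exclude_lichen: bool = True,
    weighting: str = "records",
) -> DecompositionResult:
    """Run the full deglacial decomposition on a record compilation.

    ``records`` follows the proxy-record CSV schema (see
    :mod:`c3iso.proxy_records`); ``gcm_table`` the GCM ensemble schema
    (see :mod:`c3iso.map_correction`).  The δ¹³C_CO₂ source term is
    dropped by default; with ``keep_co2_term`` it is measured from
    ``d13c_samples`` window means when given, else the canonical 0.05‰
    is used.
    """
    filtered = filter_records(
        records,
        min_c3_fraction=min_c3_fraction,
        exclude_lichen=exclude_lichen,
    )
    plant = to_plant_equivalent(filtered, offsets=offsets)
    adj = adjust_records(plant, value_col="d13c_plant")

    gm = group_means(adj, windows=windows, value_col="d13c_plant_adj")
    delta_adj = float(gm.loc["post", "mean"] - gm.loc["pre", "mean"])
    sigma_adj = quadrature([gm.loc["post", "se"], gm.loc["pre", "se"]])

    ages = adj["age_kyr_bp"].to_numpy()
    labels = _window_labels(ages, windows)
    windowed = adj[labels != ""]
    map_eff = cohort_map_effect(windowed, gcm_table, weighting=weighting)

    delta_co2iso = 0.0
    if keep_co2_term:
        if d13c_samples is not None:
            d_gm = group_means(d13c_samples, windows=windows, value_col="value")
            delta_co2iso = float(
                d_gm.loc["post", "mean"] - d_gm.loc["pre", "mean"]
            )
        else:
            delta_co2iso = CO2_ISOTOPE_TERM

    vals = adj["d13c_plant_adj"].to_numpy()
    t, p = group_shift_test(
        vals[labels == "pre"], vals[labels == "post"]
    )
    dec = decompose(
        delta_adj=delta_adj,
        delta_map=map_eff.mean,
        sigma_adj=sigma_adj,
        sigma_map=map_eff.sigma,
        delta_co2iso=delta_co2iso,
        rise_ppmv=rise_ppmv,
    )
    return DecompositionResult(
        group_means=gm,
        map_effect=map_eff,
        decomposition=dec,
        t_statistic=t,
        p_value=p,
        n_records=int(len(windowed)),
    )
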