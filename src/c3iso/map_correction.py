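"""MAP change between the LGM and mid-Holocene as an isotopic term.

A palaeoclimate GCM ensemble (PMIP3/CMIP5-style; seven models in the
reference configuration) supplies per-site mean annual precipitation at
the Last Glacial Maximum (21 kyr BP) and the mid-Holocene (6 kyr BP).
Through the precipitation term of the Kohn regression each pair converts
to the MAP contribution to the deglacial (Holocene − pre-LGM) shift in
plant δ¹³C:

    Δ(δ¹³C_MAP) = −5.6 · [log₁₀(MAP_midH + 300) − log₁₀(MAP_LGM + 300)]

**Sign convention** (read this): the value returned is the contribution
of changing MAP to the *Holocene-minus-glacial* difference of δ¹³C, so a
wetter Holocene gives a *negative* contribution (wetter → more
¹³C-depleted plants).  The antisymmetric counterpart (swap the epochs)
simply flips the sign.

Ensemble statistics are the mean and 1σ across models — the multi-model
mean being more reliable than any single member — and cohort aggregation
weighs each fossil *record* equally, so well-sampled sites carry more
weight (site-equal weighting is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SECONDS_PER_YEAR",
    "MapEffect",
    "flux_to_mm_per_year",
    "d13c_map_change",
    "ensemble_effect",
    "site_ensemble_effects",
    "cohort_map_effect",
]

#: Julian-year seconds, for converting GCM precipitation flux
#: (kg m⁻² s⁻¹ ≡ mm/s of water) to mm/yr.
SECONDS_PER_YEAR = 31_557_600.0

_COEF = 5.6
_OFFSET = 300.0


@dataclass(frozen=True)
class MapEffect:
    """Isotopic MAP contribution (‰) with inter-model uncertainty."""

    mean: float
    sigma: float
    n_models: int
    fraction_wetter: float | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def flux_to_mm_per_year(flux):
    """Convert precipitation flux (kg m⁻² s⁻¹) to MAP (mm/yr)."""
    out = np.asarray(flux, dtype=float) * SECONDS_PER_YEAR
    return out if out.ndim else float(out)


def d13c_map_change(map_lgm, map_midh):
    """MAP contribution (‰) to the Holocene − pre-LGM δ¹³C difference.

    Negative when the mid-Holocene is wetter than the LGM; antisymmetric
    under swapping the two epochs.
    """
    lgm = np.asarray(map_lgm, dtype=float)
    midh = np.asarray(map_midh, dtype=float)
    if np.any(lgm < 0) or np.any(midh < 0):
        raise ValueError("MAP values must be non-negative (mm/yr)")
    out = -_COEF * (np.log10(midh + _OFFSET) - np.log10(lgm + _OFFSET))
    return out if out.ndim else float(out)


def _dedupe(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicated (model, site) rows so weighting follows
    records, never table rows."""
    return (
        pairs.groupby(["model", "site_id"], as_index=False)[
            ["map_lgm_mm", "map_midh_mm"]
        ].mean()
    )


def ensemble_effect(pairs: pd.DataFrame) -> MapEffect:
    """Ensemble MAP effect for a single site.

    ``pairs`` holds one row per GCM with columns ``model``,
    ``map_lgm_mm``, ``map_midh_mm``.  Requires at least two models for a
    defined inter-model sigma.
    """
    if pairs["model"].nunique() < 2:
        raise ValueError("need >= 2 GCMs for an ensemble sigma")
    eff = d13c_map_change(
        pairs["map_lgm_mm"].to_numpy(), pairs["map_midh_mm"].to_numpy()
    )
    wetter = float(np.mean(pairs["map_midh_mm"].to_numpy() > pairs["map_lgm_mm"].to_numpy()))
    return MapEffect(
        mean=float(np.mean(eff)),
        sigma=float(np.std(eff, ddof=1)),
        n_models=int(pairs["model"].nunique()),
        fraction_wetter=wetter,
    )


def site_ensemble_effects(gcm_table: pd.DataFrame) -> pd.DataFrame:
    """Per-site ensemble mean and sigma of the MAP effect.

    ``gcm_table`` columns: ``model, site_id, map_lgm_mm, map_midh_mm``.
    Returns a frame indexed by ``site_id`` with ``mean``, ``sigma``,
    ``n_models``.
    """
    tab = _dedupe(gcm_table)
    tab = tab.assign(
        effect=d13c_map_change(
            tab["map_lgm_mm"].to_numpy(), tab["map_midh_mm"].to_numpy()
        )
    )
    g = tab.groupby("site_id")["effect"]
    return pd.DataFrame(
        {"mean": g.mean(), "sigma": g.std(ddof=1), "n_models": g.count()}
    )


def cohort_map_effect(
    records: pd.DataFrame,
    gcm_table: pd.DataFrame,
    weighting: str = "records",
) -> MapEffect:
    """Cohort-level MAP contribution to the deglacial shift.

    For each GCM the per-site effects are averaged with weights equal to
    the number of records at each site (``weighting="records"``, the
    default) or equally per site (``weighting="sites"``); the ensemble
    mean and 1σ are then taken across GCMs.  ``records`` must carry a
    ``site_id`` column; every site present must be covered by the GCM
    table.  Also reports the fraction of sites that the ensemble mean
    predicts to be wetter in the mid-Holocene.
    """
    if weighting not in ("records", "sites"):
        raise ValueError("weighting must be 'records' or 'sites'")
    counts = records["site_id"].value_counts()
    tab = _dedupe(gcm_table)
    missing = set(counts.index) - set(tab["site_id"])
    if missing:
        raise ValueError(f"no GCM coverage for sites: {sorted(missing)!r}")
    tab = tab[tab["site_id"].isin(counts.index)].copy()
    tab["effect"] = d13c_map_change(
        tab["map_lgm_mm"].to_numpy(), tab["map_midh_mm"].to_numpy()
    )
    if weighting == "records":
        tab["w"] = tab["site_id"].map(counts).astype(float)
    else:
        tab["w"] = 1.0
    per_model = tab.groupby("model").apply(
        lambda d: np.average(d["effect"], weights=d["w"]),
        include_groups=False,
    )
    n_models = int(per_model.size)
    if n_models < 2:
        raise ValueError("need >= 2 GCMs for an ensemble sigma")
    ens = tab.groupby("site_id")[["map_lgm_mm", "map_midh_mm"]].mean()
    frac_wetter = float((ens["map_midh_mm"] > ens["map_lgm_mm"]).mean())
    return MapEffect(
        mean=float(per_model.mean()),
        sigma=float(per_model.std(ddof=1)),
        n_models=n_models,
        fraction_wetter=frac_wetter,
    )
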