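"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of the real study inputs so the
whole analysis is testable without downloads:

* **Ice core series** — a smooth logistic deglacial ramp in pCO₂
  (190 → 270 ppmv centred on ~14 kyr BP, i.e. the ~80 ppmv rise) plus a
  gently fluctuating δ¹³C_CO₂ (±0.15‰ around −6.5‰, echoing the ≤0.3‰
  observed fluctuations), sampled irregularly with per-sample 1σ noise
  and a handful of flagged outliers.
* **Sites** — localities scattered over mid/high northern latitudes with
  smooth analytic altitude and modern-MAP fields, optionally also
  materialised as rasters that agree exactly with the per-site values.
* **Proxy records** — collagen (n = 521) and cellulose (n = 720)
  compilations, matching the real compilation sizes, built as
  ``true fractionation model(atmosphere at age)``
  ``− geographic terms + palaeo-MAP deviation + archive offset + noise``,
  with lichen-feeder and low-C3 contaminants included so the curation
  filters have work to do.
* **GCM ensemble** — seven pseudo-models whose per-site LGM and
  mid-Holocene MAP are the true values times lognormal inter-model
  noise (spread chosen so the ensemble 1σ of the isotopic effect is a
  few tenths of ‰, the magnitude seen in real PMIP ensembles).

Every random stream derives from a single scenario seed through named
sub-streams, so stages are individually reproducible.  Ground truth
(true pCO₂ effect, MAP contribution, source-isotope change, pCO₂ rise)
is returned alongside the records for parameter-recovery tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .fractionation_models import AtmosState, get_model, predict_delta_p
from .geo_adjustment import delta_alt_term, delta_lat_term, delta_map_term

__all__ = [
    "ScenarioConfig",
    "IceCoreTruth",
    "stream_rng",
    "gen_icecore",
    "gen_sites",
    "gen_records",
    "gen_gcm_ensemble",
    "generate_scenario",
]


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible RNG sub-stream derived from one scenario seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults mirror the deglacial study design: a 190 → 270 ppmv ramp,
    δ¹³C_CO₂ near −6.5‰, 521 collagen + 720 cellulose records, a
    7-member GCM ensemble, and a drier LGM (MAP × 0.75).
    """

    seed: int = 0
    # ice-core series
    age_min_kyr: float = 0.0
    age_max_kyr: float = 40.0
    pco2_glacial: float = 190.0
    pco2_holocene: float = 270.0
    ramp_center_kyr: float = 14.0
    ramp_width_kyr: float = 1.2
    n_pco2: int = 300
    pco2_sigma_ppmv: float = 1.5
    d13c_baseline: float = -6.5
    d13c_fluct_amp: float = 0.15
    d13c_fluct_period_kyr: float = 8.0
    n_d13c: int = 220
    d13c_sigma: float = 0.08
    n_outliers: int = 4
    # fractionation truth
    true_model: str = "sj2012"
    # sites
    n_sites: int = 40
    lat_mean: float = 52.0
    lat_sd: float = 8.0
    lon_mean: float = 20.0
    lon_sd: float = 35.0
    #: fixed per-site altitude / modern MAP; None -> analytic fields
    site_altitude_m: float | None = None
    site_map_mm: float | None = None
    # palaeo-MAP truth and pseudo-GCM ensemble
    lgm_map_multiplier: float = 0.75
    midh_map_multiplier: float = 1.0
    n_gcm: int = 7
    gcm_spread: float = 0.25
    gcm_site_spread: float = 0.15
    # record cohorts
    n_collagen: int = 521
    n_cellulose: int = 720
    frac_pre: float = 0.40
    frac_post: float = 0.45
    pre_window: tuple[float, float] = (20.0, 33.0)
    post_window: tuple[float, float] = (0.05, 10.0)
    record_noise: float = 1.0
    eps_diet_collagen: float = 5.1
    cellulose_leaf: float = 1.0
    gymnosperm_fraction: float = 0.6
    lichen_fraction: float = 0.05
    lichen_shift: float = 2.0
    low_c3_fraction: float = 0.03

    def __post_init__(self) -> None:
        if self.pco2_glacial <= 0 or self.pco2_holocene <= 0:
            raise ValueError("pCO2 plateaus must be positive")
        if self.n_collagen < 1 or self.n_cellulose < 1:
            raise ValueError("cohort sizes must be >= 1")
        for s in (
            self.pco2_sigma_ppmv,
            self.d13c_sigma,
            self.record_noise,
            self.gcm_spread,
        ):
            if s < 0:
                raise ValueError("noise scales must be non-negative")


@dataclass(frozen=True)
class IceCoreTruth:
    """Noise-free atmospheric history behind a synthetic scenario."""

    config: ScenarioConfig = field(repr=False)

    def pco2(self, age):
        c = self.config
        age = np.asarray(age, dtype=float)
        s = 1.0 / (1.0 + np.exp(-(age - c.ramp_center_kyr) / c.ramp_width_kyr))
        out = c.pco2_holocene + (c.pco2_glacial - c.pco2_holocene) * s
        return out if out.ndim else float(out)

    def d13c(self, age):
        c = self.config
        age = np.asarray(age, dtype=float)
        out = c.d13c_baseline + c.d13c_fluct_amp * np.sin(
            2.0 * np.pi * age / c.d13c_fluct_period_kyr
        )
        return out if out.ndim else float(out)

    def map_multiplier(self, age):
        """True MAP(age)/MAP(modern): LGM value beyond 20 kyr, the
        mid-Holocene value before 10 kyr, linear in between."""
        c = self.config
        age = np.asarray(age, dtype=float)
        w = np.clip((age - 10.0) / 10.0, 0.0, 1.0)
        out = c.midh_map_multiplier + w * (
            c.lgm_map_multiplier - c.midh_map_multiplier
        )
        return out if out.ndim else float(out)


def _altitude_field(lat, lon):
    return 350.0 + 420.0 * np.sin(np.asarray(lat) / 9.0) + 260.0 * np.cos(
        np.asarray(lon) / 17.0
    )


def _map_field(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return 350.0 + 1100.0 * np.exp(-(((lat - 45.0) / 22.0) ** 2)) * (
        0.8 + 0.2 * np.sin(lon / 25.0)
    )


def gen_icecore(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, IceCoreTruth]:
    """Synthetic pCO₂ and δ¹³C_CO₂ sample tables plus their ground truth.

    Both tables carry ``age_kyr_bp, value, sigma, core, outlier``; the
    span endpoints are always sampled so downstream grids cover the full
    scenario interval.  Outlier rows are value-shifted and flagged.
    """
    truth = IceCoreTruth(config)
    tables = []
    for name, n, sigma, fn in (
        ("pco2", config.n_pco2, config.pco2_sigma_ppmv, truth.pco2),
        ("d13c", config.n_d13c, config.d13c_sigma, truth.d13c),
    ):
        rng = stream_rng(config.seed, f"icecore-{name}")
        interior = rng.uniform(
            config.age_min_kyr, config.age_max_kyr, size=max(n - 2, 0)
        )
        ages = np.sort(
            np.concatenate(
                [[config.age_min_kyr, config.age_max_kyr], interior]
            )
        )
        values = fn(ages) + rng.normal(0.0, sigma, size=ages.size)
        df = pd.DataFrame(
            {
                "age_kyr_bp": ages,
                "value": values,
                "sigma": sigma,
                "core": rng.choice(["EDC", "EDML", "TALDICE"], size=ages.size),
                "outlier": False,
            }
        )
        if config.n_outliers > 0:
            out_ages = rng.uniform(
                config.age_min_kyr, config.age_max_kyr, size=config.n_outliers
            )
            out = pd.DataFrame(
                {
                    "age_kyr_bp": out_ages,
                    "value": fn(out_ages) + 8.0 * sigma + 5.0 * sigma,
                    "sigma": sigma,
                    "core": "EDML",
                    "outlier": True,
                }
            )
            df = pd.concat([df, out], ignore_index=True)
        tables.append(df.sort_values("age_kyr_bp", ignore_index=True))
    return tables[0], tables[1], truth


def gen_sites(
    config: ScenarioConfig, with_rasters: bool = False
):
    """Synthetic localities (and, optionally, consistent rasters).

    Site altitude and modern MAP are smooth analytic fields of lat/lon.
    With ``with_rasters=True`` the same fields are materialised on a
    0.5° grid and the per-site values are read from the nearest raster
    cell, so raster lookups and direct values agree exactly.
    """
    if config.n_sites < 1:
        raise ValueError("need at least one site")
    rng = stream_rng(config.seed, "sites")
    lat = np.clip(
        rng.normal(config.lat_mean, config.lat_sd, config.n_sites), 30.0, 75.0
    )
    lon = np.clip(
        rng.normal(config.lon_mean, config.lon_sd, config.n_sites),
        -130.0, 150.0,
    )
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(config.n_sites)],
            "lat": lat,
            "lon": lon,
        }
    )
    if not with_rasters:
        sites["altitude_m"] = (
            _altitude_field(lat, lon)
            if config.site_altitude_m is None
            else config.site_altitude_m
        )
        sites["map_mm"] = (
            _map_field(lat, lon)
            if config.site_map_mm is None
            else config.site_map_mm
        )
        return sites

    res = 0.5
    glat = np.arange(lat.min() - 2.0, lat.max() + 2.0, res)
    glon = np.arange(lon.min() - 2.0, lon.max() + 2.0, res)
    lon2d, lat2d = np.meshgrid(glon, glat)
    rasters = {
        "altitude": xr.DataArray(
            _altitude_field(lat2d, lon2d),
            coords={"lat": glat, "lon": glon},
            dims=("lat", "lon"),
        ),
        "map": xr.DataArray(
            _map_field(lat2d, lon2d),
            coords={"lat": glat, "lon": glon},
            dims=("lat", "lon"),
        ),
    }
    ilat = np.abs(glat[:, None] - lat[None, :]).argmin(axis=0)
    ilon = np.abs(glon[:, None] - lon[None, :]).argmin(axis=0)
    sites["altitude_m"] = rasters["altitude"].values[ilat, ilon]
    sites["map_mm"] = rasters["map"].values[ilat, ilon]
    return sites, rasters


def _paleo_map_term(map_mm, mult):
    """δ¹³C deviation (‰) of a site at palaeo-MAP = modern × mult."""
    map_mm = np.asarray(map_mm, dtype=float)
    return -5.6 * (np.log10(map_mm * mult + 300.0) - np.log10(map_mm + 300.0))


def gen_records(
    config: ScenarioConfig,
    truth: IceCoreTruth,
    sites: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic proxy compilation plus the injected ground truth.

    Each record is the true fractionation model evaluated on the true
    atmosphere at its age, moved *out* of the reference environment by
    the inverse Kohn terms of its site, shifted by the site's palaeo-MAP
    deviation at that age, converted to its archive (collagen +5.1‰,
    cellulose +1.0‰), and jittered with Gaussian noise.  Lichen feeders
    and low-C3 sites receive additional positive shifts and are meant to
    be removed by curation.

    The returned truth dict holds the injected deglacial quantities
    evaluated on the curated pre/post cohorts: ``delta_pco2`` (at fixed
    δ¹³C_CO₂), ``delta_co2iso``, ``delta_map``, ``rise_ppmv`` and
    ``per100``.
    """
    c = config
    model = get_model(c.true_model)
    rng = stream_rng(c.seed, "records")
    rows = []
    for archive, n in (("collagen", c.n_collagen), ("cellulose", c.n_cellulose)):
        u = rng.uniform(size=n)
        ages = np.where(
            u < c.frac_pre,
            rng.uniform(*c.pre_window, size=n),
            np.where(
                u < c.frac_pre + c.frac_post,
                rng.uniform(*c.post_window, size=n),
                rng.uniform(c.post_window[1], c.pre_window[0], size=n),
            ),
        )
        idx = rng.integers(0, len(sites), size=n)
        site = sites.iloc[idx].reset_index(drop=True)

        leaf_ref = np.asarray(
            predict_delta_p(
                model, AtmosState(truth.pco2(ages), truth.d13c(ages))
            )
        )
        d_geo = (
            delta_map_term(site["map_mm"].to_numpy())
            + delta_alt_term(site["altitude_m"].to_numpy())
            + delta_lat_term(site["lat"].to_numpy())
        )
        m_t = _paleo_map_term(
            site["map_mm"].to_numpy(), truth.map_multiplier(ages)
        )
        offset = (
            c.eps_diet_collagen if archive == "collagen" else c.cellulose_leaf
        )
        d13c = (
            leaf_ref
            - d_geo
            + m_t
            + offset
            + rng.normal(0.0, c.record_noise, size=n)
        )

        if archive == "collagen":
            taxon = rng.choice(
                ["Bos", "Cervus", "Equus"], size=n
            ).astype(object)
            lichen = rng.uniform(size=n) < c.lichen_fraction
            taxon[lichen] = "Rangifer"
            d13c = d13c + np.where(lichen, c.lichen_shift, 0.0)
        else:
            gym = rng.uniform(size=n) < c.gymnosperm_fraction
            taxon = np.where(gym, "gymnosperm", "mixed/unidentified")
            lichen = np.zeros(n, dtype=bool)

        c3 = np.full(n, 0.995)
        low = rng.uniform(size=n) < c.low_c3_fraction
        c3[low] = rng.uniform(0.6, 0.89, size=int(low.sum()))
        d13c = d13c + np.where(low, (1.0 - c3) * 14.0, 0.0)

        rows.append(
            pd.DataFrame(
                {
                    "id": [f"{archive[:3]}{i:04d}" for i in range(n)],
                    "archive": archive,
                    "taxon_group": taxon,
                    "age_kyr_bp": ages,
                    "age_sigma_kyr": rng.uniform(0.05, 0.3, size=n),
                    "d13c": d13c,
                    "site_id": site["site_id"].to_numpy(),
                    "lat": site["lat"].to_numpy(),
                    "lon": site["lon"].to_numpy(),
                    "altitude_m": site["altitude_m"].to_numpy(),
                    "map_mm": site["map_mm"].to_numpy(),
                    "c3_fraction": c3,
                    "lichen_feeder": lichen,
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)

    clean = records[
        (records["c3_fraction"] >= 0.9) & ~records["lichen_feeder"]
    ]
    pre = clean[clean["age_kyr_bp"] >= 20.0]
    post = clean[
        (clean["age_kyr_bp"] >= 0.2) & (clean["age_kyr_bp"] < 10.0)
    ]
    fixed = c.d13c_baseline
    mean_p = {
        w: float(
            np.mean(
                np.asarray(
                    predict_delta_p(
                        model,
                        AtmosState(truth.pco2(g["age_kyr_bp"].to_numpy()), fixed),
                    )
                )
            )
        )
        for w, g in (("pre", pre), ("post", post))
    }
    rise = float(
        np.mean(truth.pco2(post["age_kyr_bp"].to_numpy()))
        - np.mean(truth.pco2(pre["age_kyr_bp"].to_numpy()))
    )
    delta_pco2 = mean_p["post"] - mean_p["pre"]
    delta_co2iso = float(
        np.mean(truth.d13c(post["age_kyr_bp"].to_numpy()))
        - np.mean(truth.d13c(pre["age_kyr_bp"].to_numpy()))
    )
    delta_map = float(
        np.mean(
            _paleo_map_term(
                post["map_mm"].to_numpy(),
                truth.map_multiplier(post["age_kyr_bp"].to_numpy()),
            )
        )
        - np.mean(
            _paleo_map_term(
                pre["map_mm"].to_numpy(),
                truth.map_multiplier(pre["age_kyr_bp"].to_numpy()),
            )
        )
    )
    truth_dict = {
        "delta_pco2": delta_pco2,
        "delta_co2iso": delta_co2iso,
        "delta_map": delta_map,
        "rise_ppmv": rise,
        "per100": delta_pco2 * 100.0 / rise,
        "true_model": c.true_model,
    }
    return records, truth_dict


def gen_gcm_ensemble(
    config: ScenarioConfig, sites: pd.DataFrame
) -> pd.DataFrame:
    """Pseudo-GCM ensemble MAP table: ``model, site_id, map_lgm_mm,
    map_midh_mm``.

    Each of ``n_gcm`` pseudo-models reports the true epoch MAP (modern ×
    epoch multiplier) times lognormal noise with two components: a
    model-level log-bias (sd ``gcm_spread``, shared by all sites of one
    model and epoch — real GCMs disagree systematically, which is what
    sets the inter-model spread of cohort effects) and independent
    per-site jitter (sd ``gcm_site_spread``).
    """
    if config.n_gcm < 2:
        raise ValueError("need at least 2 pseudo-GCMs")
    rng = stream_rng(config.seed, "gcm")
    rows = []
    for j in range(config.n_gcm):
        bias = rng.normal(0.0, config.gcm_spread, size=2)
        eps = rng.normal(0.0, config.gcm_site_spread, size=(len(sites), 2))
        rows.append(
            pd.DataFrame(
                {
                    "model": f"gcm{j + 1:02d}",
                    "site_id": sites["site_id"].to_numpy(),
                    "map_lgm_mm": sites["map_mm"].to_numpy()
                    * config.lgm_map_multiplier
                    * np.exp(bias[0] + eps[:, 0]),
                    "map_midh_mm": sites["map_mm"].to_numpy()
                    * config.midh_map_multiplier
                    * np.exp(bias[1] + eps[:, 1]),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_scenario(config: ScenarioConfig | None = None, **overrides):
    """One-call scenario: all four inputs plus ground truth.

    Returns a dict with keys ``pco2_samples, d13c_samples, icecore_truth,
    sites, records, gcm, truth``.
    """
    if config is None:
        config = ScenarioConfig()
    if overrides:
        config = replace(config, **overrides)
    pco2, d13c, truth = gen_icecore(config)
    sites = gen_sites(config)
    records, truth_dict = gen_records(config, truth, sites)
    gcm = gen_gcm_ensemble(config, sites)
    return {
        "config": config,
        "pco2_samples": pco2,
        "d13c_samples": d13c,
        "icecore_truth": truth,
        "sites": sites,
        "records": records,
        "gcm": gcm,
        "truth": truth_dict,
    }
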