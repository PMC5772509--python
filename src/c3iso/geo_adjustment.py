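"""Adjustment of fossil δ¹³C for geographic variability.

Modern C3 plant δ¹³C varies systematically with mean annual precipitation
(MAP), altitude and latitude (the Kohn regressions).  To make widely
scattered fossil records comparable, every measurement is shifted to a
common reference environment — MAP = 1000 mm/yr, altitude = 840 m,
latitude = 50°N — by adding

    δ′ = δ_MAP + δ_alt + δ_lat

where

    δ_MAP = 5.6·(log₁₀(MAP + 300) − log₁₀(1300))
    δ_alt = 0.00019·(840 − altitude)
    δ_lat = 0.0124·(|latitude| − 50)

All three terms vanish at the reference point and the adjustment is
exactly invertible.  Site altitude and modern MAP can be supplied
directly or looked up (nearest cell) in gridded rasters held as
``xarray.DataArray`` objects with ``lat``/``lon`` coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "REFERENCE_MAP_MM",
    "REFERENCE_ALT_M",
    "REFERENCE_LAT_DEG",
    "SiteLocation",
    "AdjustmentTerms",
    "delta_map_term",
    "delta_alt_term",
    "delta_lat_term",
    "adjust",
    "adjust_records",
    "raster_lookup",
]

REFERENCE_MAP_MM = 1000.0
REFERENCE_ALT_M = 840.0
REFERENCE_LAT_DEG = 50.0

_MAP_COEF = 5.6          # permil per decade of (MAP + 300)
_MAP_OFFSET_MM = 300.0
_ALT_COEF = 0.00019      # permil per metre
_LAT_COEF = 0.0124       # permil per degree of |latitude|
_LOWEST_LAND_M = -430.0  # Dead Sea shore; warn below


@dataclass(frozen=True)
class SiteLocation:
    """Geographic context of a fossil locality."""

    latitude: float
    longitude: float
    altitude: float
    map_modern: float

    def __post_init__(self) -> None:
        if abs(self.latitude) > 90.0:
            raise ValueError("|latitude| must be <= 90 degrees")
        if self.map_modern < 0.0:
            raise ValueError("modern MAP must be non-negative (mm/yr)")
        if self.altitude < _LOWEST_LAND_M:
            warnings.warn(
                f"altitude {self.altitude} m is below the lowest land "
                "surface", stacklevel=2,
            )


@dataclass(frozen=True)
class AdjustmentTerms:
    """The three Kohn terms and their sum δ′ (all ‰)."""

    d_map: float
    d_alt: float
    d_lat: float

    @property
    def d_total(self) -> float:
        return self.d_map + self.d_alt + self.d_lat


def delta_map_term(map_modern):
    """δ_MAP (‰): precipitation term of the adjustment to 1000 mm/yr."""
    m = np.asarray(map_modern, dtype=float)
    if np.any(m < 0):
        raise ValueError("MAP must be non-negative (mm/yr)")
    out = _MAP_COEF * (
        np.log10(m + _MAP_OFFSET_MM)
        - np.log10(REFERENCE_MAP_MM + _MAP_OFFSET_MM)
    )
    return out if out.ndim else float(out)


def delta_alt_term(altitude):
    """δ_alt (‰): altitude term of the adjustment to 840 m."""
    a = np.asarray(altitude, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("altitude must be finite (m)")
    out = _ALT_COEF * (REFERENCE_ALT_M - a)
    return out if out.ndim else float(out)


def delta_lat_term(latitude):
    """δ_lat (‰): latitude term, symmetric between hemispheres."""
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("|latitude| must be <= 90 degrees")
    out = _LAT_COEF * (np.abs(lat) - REFERENCE_LAT_DEG)
    return out if out.ndim else float(out)


def adjust(d13c: float, site: SiteLocation) -> tuple[float, AdjustmentTerms]:
    """Shift one δ¹³C value (‰) to the reference environment.

    Returns the adjusted value and the individual terms; subtracting
    ``terms.d_total`` recovers the input exactly.
    """
    terms = AdjustmentTerms(
        d_map=delta_map_term(site.map_modern),
        d_alt=delta_alt_term(site.altitude),
        d_lat=delta_lat_term(site.latitude),
    )
    return d13c + terms.d_total, terms


def adjust_records(
    records: pd.DataFrame, value_col: str = "d13c"
) -> pd.DataFrame:
    """Vectorised adjustment of a record table.

    ``records`` needs columns ``lat``, ``altitude_m``, ``map_mm`` and
    ``value_col``.  Returns a copy with ``d_map``, ``d_alt``, ``d_lat``
    and ``<value_col>_adj`` columns added.
    """
    out = records.copy()
    out["d_map"] = delta_map_term(out["map_mm"].to_numpy())
    out["d_alt"] = delta_alt_term(out["altitude_m"].to_numpy())
    out["d_lat"] = delta_lat_term(out["lat"].to_numpy())
    out[f"{value_col}_adj"] = (
        out[value_col] + out["d_map"] + out["d_alt"] + out["d_lat"]
    )
    return out


def raster_lookup(grid: xr.DataArray, lat: float, lon: float) -> float:
    """Nearest-cell value of a lat/lon raster at a site.

    Out-of-bounds coordinates (beyond half a cell past the grid edge) and
    missing-data cells raise ``ValueError``.  Nearest-cell (rather than
    interpolated) lookup keeps results reproducible across raster
    resolutions.
    """
    for dim in ("lat", "lon"):
        if dim not in grid.coords:
            raise ValueError(f"raster must carry a {dim!r} coordinate")
    lats = grid["lat"].values
    lons = grid["lon"].values
    half_lat = np.median(np.abs(np.diff(np.sort(lats)))) / 2 if lats.size > 1 else 0.0
    half_lon = np.median(np.abs(np.diff(np.sort(lons)))) / 2 if lons.size > 1 else 0.0
    if not (lats.min() - half_lat <= lat <= lats.max() + half_lat):
        raise ValueError(f"latitude {lat} outside raster bounds")
    if not (lons.min() - half_lon <= lon <= lons.max() + half_lon):
        raise ValueError(f"longitude {lon} outside raster bounds")
    val = float(grid.sel(lat=lat, lon=lon, method="nearest").values)
    if not np.isfinite(val):
        raise ValueError(
            f"raster has no data in the cell nearest ({lat}, {lon})"
        )
    return val
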