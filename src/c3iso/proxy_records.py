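"""Curation of the collagen and cellulose δ¹³C compilations.

Records live in a pandas DataFrame with (at least) the columns

    id, archive, taxon_group, age_kyr_bp, age_sigma_kyr, d13c,
    lat, lon, altitude_m, map_mm, c3_fraction, lichen_feeder

where ``archive`` is ``collagen`` or ``cellulose`` and ages are
calibrated kyr BP (BP = 1950 CE; calibration itself happens upstream).

Curation mirrors standard practice for deglacial compilations:

* keep only sites with predominantly C3 vegetation (``c3_fraction`` ≥ 0.9);
* drop lichen-consuming taxa (e.g. *Rangifer tarandus*), whose diet
  carries a non-vascular-plant isotopic signal;
* exclude the industrial era (ages < 0.2 kyr BP, i.e. after ~1750 CE)
  from time-window statistics, since the anthropogenic CO₂ transient
  dominates there.

Tissue conversions to plant(leaf)-equivalent values subtract the
collagen–diet enrichment ε* = 5.1‰ from collagen and the ~1‰
cellulose–bulk-leaf offset from cellulose (bulk leaf is ¹³C-depleted
relative to cellulose; the sign is fixed by requiring Holocene collagen
− 5.1 and cellulose − 1 to agree).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OffsetConstants",
    "INDUSTRIAL_CUTOFF_KYR",
    "DEFAULT_WINDOWS",
    "collagen_to_plant",
    "cellulose_to_leaf",
    "to_plant_equivalent",
    "filter_records",
    "group_means",
]

logger = logging.getLogger(__name__)

INDUSTRIAL_CUTOFF_KYR = 0.2

#: Age windows (kyr BP, half-open [young, old)) for the deglacial contrast:
#: the post-glacial window excludes the industrial era.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "post": (INDUSTRIAL_CUTOFF_KYR, 10.0),
    "pre": (20.0, np.inf),
}


@dataclass(frozen=True)
class OffsetConstants:
    """Tissue-offset constants (‰), both subtracted toward leaf values."""

    eps_diet_collagen: float = 5.1
    cellulose_leaf: float = 1.0

    def __post_init__(self) -> None:
        if self.eps_diet_collagen < 0 or self.cellulose_leaf < 0:
            raise ValueError("tissue offsets must be non-negative")


def collagen_to_plant(d13c_collagen, eps: float = 5.1):
    """Shift herbivore collagen δ¹³C to its plant-diet equivalent (‰)."""
    out = np.asarray(d13c_collagen, dtype=float) - eps
    return out if out.ndim else float(out)


def cellulose_to_leaf(d13c_cellulose, offset: float = 1.0):
    """Shift α-cellulose δ¹³C to bulk-leaf equivalent (‰)."""
    out = np.asarray(d13c_cellulose, dtype=float) - offset
    return out if out.ndim else float(out)


def to_plant_equivalent(
    records: pd.DataFrame,
    offsets: OffsetConstants = OffsetConstants(),
    value_col: str = "d13c",
    out_col: str = "d13c_plant",
) -> pd.DataFrame:
    """Add a leaf-equivalent δ¹³C column based on each record's archive."""
    archives = records["archive"].to_numpy()
    unknown = set(archives) - {"collagen", "cellulose"}
    if unknown:
        raise ValueError(f"unknown archive labels: {sorted(unknown)}")
    shift = np.where(
        archives == "collagen",
        offsets.eps_diet_collagen,
        offsets.cellulose_leaf,
    )
    out = records.copy()
    out[out_col] = out[value_col].to_numpy() - shift
    return out


def filter_records(
    records: pd.DataFrame,
    min_c3_fraction: float | None = 0.9,
    exclude_lichen: bool = True,
    age_window: tuple[float, float] | None = None,
    exclude_industrial: bool = True,
) -> pd.DataFrame:
    """Apply the curation rules; returns the surviving subset.

    Rules are independent and idempotent; the number of records removed
    by each active rule is logged.  Passing ``None``/``False`` disables a
    rule.  ``age_window`` is (young, old) in kyr BP, half-open on the old
    side.  An empty result is allowed (warned, not raised).
    """
    keep = pd.Series(True, index=records.index)
    if min_c3_fraction is not None and "c3_fraction" in records:
        rule = records["c3_fraction"] >= min_c3_fraction
        logger.info("c3-fraction filter removed %d records", int((~rule & keep).sum()))
        keep &= rule
    if exclude_lichen and "lichen_feeder" in records:
        rule = ~records["lichen_feeder"].astype(bool)
        logger.info("lichen-feeder filter removed %d records", int((~rule & keep).sum()))
        keep &= rule
    if exclude_industrial:
        rule = records["age_kyr_bp"] >= INDUSTRIAL_CUTOFF_KYR
        logger.info("industrial-era filter removed %d records", int((~rule & keep).sum()))
        keep &= rule
    if age_window is not None:
        young, old = age_window
        rule = (records["age_kyr_bp"] >= young) & (records["age_kyr_bp"] < old)
        logger.info("age-window filter removed %d records", int((~rule & keep).sum()))
        keep &= rule
    out = records.loc[keep]
    if out.empty:
        logger.warning("all %d records removed by filters", len(records))
    return out


def group_means(
    records: pd.DataFrame,
    windows: dict[str, tuple[float, float]] = DEFAULT_WINDOWS,
    value_col: str = "d13c",
) -> pd.DataFrame:
    """Per-window mean, sd, n and standard error of a δ¹³C column.

    ``windows`` maps window name to (young, old) kyr BP bounds, selecting
    young ≤ age < old (unweighted arithmetic statistics).  An empty
    window raises ``ValueError``.
    """
    ages = records["age_kyr_bp"].to_numpy()
    vals = records[value_col].to_numpy()
    rows = {}
    for name, (young, old) in windows.items():
        sel = (ages >= young) & (ages < old)
        n = int(sel.sum())
        if n == 0:
            raise ValueError(f"age window {name!r} = {(young, old)} is empty")
        v = vals[sel]
        sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
        rows[name] = {
            "mean": float(np.mean(v)),
            "sd": sd,
            "n": n,
            "se": sd / np.sqrt(n) if n > 1 else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
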