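"""Regional and national roll-up, storage-area regression, extrapolation.

Provincial pool breakdowns are summed to regions and the nation; carbon
density is total stock over total area; pool fractions are pool sums over
the total, so the national fractions are automatically the total-weighted
means of the regional ones.  A linear regression of provincial storage on
urban area gives a "specific urban carbon storage" (Tg C per 1,000 km^2)
that can be extrapolated to any aggregate urban area, e.g. the global
urban extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core_model import KG_PER_TG, M2_PER_KM2, POOL_NAMES, ValidationError
from .uncertainty import UncertaintyResult, combine_provinces

__all__ = [
    "RegressionFit",
    "NATIONAL_ROW",
    "carbon_density",
    "aggregate",
    "national_fractions_from_regions",
    "fit_storage_area",
    "extrapolate_global",
    "context_ratios",
    "DEFAULT_NATIONAL_STOCK_PG",
    "DEFAULT_NATIONAL_AREA_KM2",
]

NATIONAL_ROW = "China"

# cited national terrestrial-ecosystem context, overridable per call
DEFAULT_NATIONAL_STOCK_PG = 77.4       # Pg C in terrestrial ecosystems
DEFAULT_NATIONAL_AREA_KM2 = 9.60e6     # national land area, km^2

_POOL_COLS = {"vegetation": "c_veg", "soil": "c_soil",
              "humans": "c_human", "buildings": "c_building"}


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of provincial storage (Tg C) on urban area (1,000 km^2)."""

    slope: float        # Tg C per 1,000 km^2
    intercept: float    # Tg C (0 when fit through the origin)
    r_squared: float
    n: int


def carbon_density(total_tg: float, area_km2: float) -> float:
    """Carbon density in kg C m^-2 from a stock in Tg C over an area in km^2."""
    if area_km2 <= 0:
        raise ValidationError(f"area must be > 0 to form a density, got {area_km2!r}")
    return total_tg * KG_PER_TG / (area_km2 * M2_PER_KM2)


def _summary_row(label: str, sub: pd.DataFrame) -> dict:
    area = float(sub["area_urban"].sum())
    total = float(sub["c_total"].sum())
    row = {"region": label, "area": area, "total": total,
           "density": carbon_density(total, area)}
    for pool, col in _POOL_COLS.items():
        row[col] = float(sub[col].sum())
        row[f"frac_{pool}"] = row[col] / total if total > 0 else 0.0
    return row


def aggregate(pool_df: pd.DataFrame, mc_results: dict | None = None) -> pd.DataFrame:
    """Region rows plus a national row from per-province pool breakdowns.

    ``pool_df`` is the output of :func:`urbancarbon.core_model.pools_table`
    (every province must carry a region label).  If ``mc_results`` maps
    province ids to :class:`UncertaintyResult` objects, draws are summed
    within regions and nationally and 95% half-width columns are added for
    the total and the density.
    """
    if pool_df["region"].isna().any():
        missing = pool_df.loc[pool_df["region"].isna(), "province_id"].tolist()
        raise ValidationError(f"provinces without a region label: {missing}")
    rows = [
        _summary_row(region, sub)
        for region, sub in pool_df.groupby("region", sort=True)
    ]
    rows.append(_summary_row(NATIONAL_ROW, pool_df))
    out = pd.DataFrame(rows)

    if mc_results is not None:
        missing = set(pool_df["province_id"]) - set(mc_results)
        if missing:
            raise ValidationError(f"provinces without MC results: {sorted(missing)}")
        hw = {}
        for region, sub in pool_df.groupby("region", sort=True):
            combined = combine_provinces(
                [mc_results[pid] for pid in sub["province_id"]], label=region
            )
            hw[region] = combined.half_width_95
        national = combine_provinces(list(mc_results.values()), label=NATIONAL_ROW)
        hw[NATIONAL_ROW] = national.half_width_95
        out["total_hw95"] = out["region"].map(hw)
        out["density_hw95"] = out["total_hw95"] * KG_PER_TG / (out["area"] * M2_PER_KM2)
    return out


def national_fractions_from_regions(region_fracs, region_totals) -> np.ndarray:
    """National pool shares as the total-weighted mean of regional shares.

    ``region_fracs`` is (n_regions, n_pools) with shares in [0, 1] (or all
    in percent — the output keeps the input scale); ``region_totals`` the
    regional carbon totals used as weights.
    """
    fracs = np.asarray(region_fracs, dtype=float)
    totals = np.asarray(region_totals, dtype=float)
    if (totals < 0).any():
        raise ValidationError("region totals must be >= 0")
    grand = totals.sum()
    if grand == 0:
        raise ValidationError("zero grand total; national fractions undefined")
    return fracs.T @ totals / grand


def fit_storage_area(
    totals_tg,
    areas_km2,
    through_origin: bool = False,
) -> RegressionFit:
    """OLS of provincial carbon storage on urban area.

    Areas are expressed in units of 1,000 km^2 so the slope reads directly
    as Tg C per 1,000 km^2 of urban land.  Zero-area provinces are
    excluded.  ``through_origin=True`` drops the intercept (the ratio-like
    "specific storage" convention).
    """
    totals = np.asarray(totals_tg, dtype=float)
    areas = np.asarray(areas_km2, dtype=float)
    keep = areas > 0
    totals, areas = totals[keep], areas[keep]
    if len(totals) < 3:
        raise ValidationError(f"need >= 3 provinces with positive area, got {len(totals)}")
    x = areas / 1000.0
    if np.ptp(x) == 0:
        raise ValidationError("all urban areas identical; regression is degenerate")
    X = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(totals, X).fit()
    if through_origin:
        slope, intercept = float(fit.params[0]), 0.0
    else:
        intercept, slope = float(fit.params[0]), float(fit.params[1])
    return RegressionFit(slope=slope, intercept=intercept,
                         r_squared=float(fit.rsquared), n=len(totals))


def extrapolate_global(slope: float, area_lo_km2: float, area_hi_km2: float) -> tuple:
    """Global urban carbon storage bounds, Pg C, from a specific storage slope.

    ``slope`` is in Tg C per 1,000 km^2; the bounds are the low and high
    estimates of global urban extent in km^2.
    """
    if slope < 0:
        raise ValidationError(f"slope must be >= 0, got {slope}")
    if area_lo_km2 > area_hi_km2:
        raise ValidationError("area_lo must be <= area_hi")
    lo = slope * (area_lo_km2 / 1000.0) / 1000.0   # Tg -> Pg
    hi = slope * (area_hi_km2 / 1000.0) / 1000.0
    return lo, hi


def context_ratios(
    urban_total_tg: float,
    urban_area_km2: float,
    national_stock_pg: float = DEFAULT_NATIONAL_STOCK_PG,
    national_area_km2: float = DEFAULT_NATIONAL_AREA_KM2,
) -> tuple:
    """Urban share of national carbon stock and land area, and their ratio.

    Returns ``(stock_share_pct, area_share_pct, density_ratio)`` where
    ``density_ratio`` is the urban carbon density over the national
    average density and equals stock_share / area_share identically.
    """
    if national_stock_pg <= 0 or national_area_km2 <= 0 or urban_area_km2 <= 0:
        raise ValidationError("denominators must be > 0 for context ratios")
    stock_share = 100.0 * (urban_total_tg / 1000.0) / national_stock_pg
    area_share = 100.0 * urban_area_km2 / national_area_km2
    return stock_share, area_share, stock_share / area_share
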