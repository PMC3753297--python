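"""Synthetic provincial-statistics tables for exercising the pipeline.

The real analysis consumes a yearbook-style table — one row per province
with urban area, green-space share, three carbon densities, population,
floor areas and furniture ownership — that has no public machine-readable
release.  This module generates tables with the same structure and
realistic covariation so every stage of the pipeline runs and can be
tested end to end:

* urban areas are heavy-tailed (log-normal) and rescaled to a national
  target, so a few large provinces dominate, spanning ~2 orders of
  magnitude;
* green fractions are uniform around the national figure of 31%;
* carbon densities are log-normal within configured ranges (the range is
  read as a central 95% interval on the log scale);
* population scales with area through a drawn urban population density,
  and floor areas and household counts derive from population, so the
  anthropogenic pools co-vary with area as they do in real statistics.

``calibrate_national`` rescales one generated table, pool by pool and in
closed form, so the national point-estimate run reproduces a target total
and pool partitioning exactly — the standard fixture for end-to-end
checks against published national aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import ModelConstants, ProvinceInputs, ValidationError, pools_table

__all__ = ["GeneratorConfig", "generate_provinces", "calibrate_national"]

#: the six conventional macro-regions with their province counts (sums to 31)
DEFAULT_REGIONS = {
    "North": 5,
    "Northeast": 3,
    "East": 7,
    "Central-south": 6,
    "Southwest": 5,
    "Northwest": 5,
}

# national aggregates used by the calibrated fixture
CALIBRATION_TOTAL_TG = 577.0
CALIBRATION_FRACTIONS = {
    "vegetation": 0.073,
    "soil": 0.561,
    "humans": 0.010,
    "buildings": 0.356,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic provincial-statistics generator.

    Ranges are (low, high) in the variable's natural units and are read as
    central 95% intervals of a log-normal on the log scale.  Defaults:
    31 provinces in the six macro-regions; national urban area 33,697 km^2;
    green fraction uniform 0.31 +/- 0.14; vegetation density 0.4-2.5 and
    soil densities 5-15 (green) / 4-12 (impervious) kg C m^-2, which keep
    provincial urban carbon densities within the observed 9-29 kg C m^-2
    envelope; urban population density 8,000-25,000 km^-2; 35 m^2 total
    floor space per capita; 3 persons per household.
    """

    n_provinces: int = 31
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    seed: int = 0
    national_area_target: float = 33_697.0      # km^2
    national_green_frac: float = 0.31
    green_frac_half_width: float = 0.14
    area_log_sd: float = 1.0
    d_green_range: tuple = (0.4, 2.5)           # kg C m^-2
    d_sgreen_range: tuple = (5.0, 15.0)         # kg C m^-2
    d_simp_range: tuple = (4.0, 12.0)           # kg C m^-2
    sd_simp_cv: float = 0.3                     # sd_simp = cv x d_simp
    pop_density_range: tuple = (8_000.0, 25_000.0)   # persons km^-2
    per_capita_floor: float = 35.0              # m^2 per person, all buildings
    resid_floor_frac_range: tuple = (0.5, 0.8)  # residential share of floor area
    n_set_range: tuple = (0.5, 2.0)             # furniture sets per household
    household_size: float = 3.0                 # persons per household

    def __post_init__(self) -> None:
        if self.n_provinces < 1:
            raise ValidationError("n_provinces must be >= 1")
        if sum(self.regions.values()) != self.n_provinces:
            raise ValidationError(
                f"region province counts {self.regions} must sum to n_provinces={self.n_provinces}"
            )
        if self.national_area_target <= 0 or self.per_capita_floor <= 0 or self.household_size <= 0:
            raise ValidationError("area target, floor space and household size must be > 0")
        for name in ("d_green_range", "d_sgreen_range", "d_simp_range",
                     "pop_density_range", "resid_floor_frac_range", "n_set_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be positive and ordered, got {(lo, hi)}")
        if not 0 < self.national_green_frac < 1:
            raise ValidationError("national_green_frac must lie in (0, 1)")
        if (self.national_green_frac - self.green_frac_half_width <= 0
                or self.national_green_frac + self.green_frac_half_width >= 1):
            raise ValidationError("green fraction range must stay inside (0, 1)")


def _lognormal_in_range(rng, rng_pair, size):
    """Log-normal draws whose central 95% interval is the given range."""
    lo, hi = rng_pair
    mu = 0.5 * (np.log(lo) + np.log(hi))
    sigma = (np.log(hi) - np.log(lo)) / (2 * 1.959963984540054)
    return rng.lognormal(mu, sigma, size=size)


def generate_provinces(cfg: GeneratorConfig) -> tuple:
    """Draw a province-inputs table and its generating ground truth.

    Returns ``(table, truth)``: the table validates row-wise as
    :class:`ProvinceInputs`; ``truth`` records the latent draws (raw
    areas, population densities, floor fractions) and the generator's own
    straight-arithmetic national pool totals, for closed-loop recovery
    tests against the pipeline.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_provinces

    raw_area = rng.lognormal(mean=0.0, sigma=cfg.area_log_sd, size=n)
    area = raw_area / raw_area.sum() * cfg.national_area_target
    green = rng.uniform(cfg.national_green_frac - cfg.green_frac_half_width,
                        cfg.national_green_frac + cfg.green_frac_half_width, size=n)
    d_green = _lognormal_in_range(rng, cfg.d_green_range, n)
    d_sgreen = _lognormal_in_range(rng, cfg.d_sgreen_range, n)
    d_simp = _lognormal_in_range(rng, cfg.d_simp_range, n)
    pop_density = _lognormal_in_range(rng, cfg.pop_density_range, n)
    pop = area * pop_density
    floor_total = pop * cfg.per_capita_floor / 1e4          # 10^4 m^2
    resid_frac = rng.uniform(*cfg.resid_floor_frac_range, size=n)
    floor_resid = floor_total * resid_frac
    n_household = pop / cfg.household_size
    n_set = rng.uniform(*cfg.n_set_range, size=n)

    region_labels = np.repeat(list(cfg.regions), list(cfg.regions.values()))
    table = pd.DataFrame({
        "province_id": [f"P{i + 1:02d}" for i in range(n)],
        "region": region_labels,
        "area_urban": area,
        "green_frac": green,
        "d_green": d_green,
        "d_sgreen": d_sgreen,
        "d_simp": d_simp,
        "sd_simp": cfg.sd_simp_cv * d_simp,
        "pop_urban": pop,
        "floor_resid": floor_resid,
        "floor_total": floor_total,
        "n_set": n_set,
        "n_household": n_household,
    })
    for _, row in table.iterrows():
        ProvinceInputs.from_row(row)   # raises if the generator broke an invariant

    # independent straight-arithmetic bookkeeping of what was generated
    c = ModelConstants()
    veg_kg = (area * 1e6 * green * d_green).sum()
    soil_kg = (area * 1e6 * (green * d_sgreen + (1 - green) * d_simp)).sum()
    human_kg = (pop * c.weight_ave * c.f1 * c.f2).sum()
    constr_kg = ((floor_resid * c.f3 + (floor_total - floor_resid) * c.f5)
                 * 1e4 * c.f4 * 1e3 * c.f2).sum()
    furn_kg = (n_set * n_household * c.f6 * (c.f7 * c.f8 + c.f9 * c.f10)
               * c.f4 * 1e3 * c.f2).sum()
    truth = {
        "config": cfg,
        "raw_area": raw_area,
        "pop_density": pop_density,
        "resid_frac": resid_frac,
        "national_pools_tg": {
            "vegetation": veg_kg / 1e9,
            "soil": soil_kg / 1e9,
            "humans": human_kg / 1e9,
            "buildings": (constr_kg + furn_kg) / 1e9,
            "total": (veg_kg + soil_kg + human_kg + constr_kg + furn_kg) / 1e9,
        },
    }
    return table, truth


def calibrate_national(
    cfg: GeneratorConfig | None = None,
    constants: ModelConstants | None = None,
    total_tg: float = CALIBRATION_TOTAL_TG,
    fractions: dict | None = None,
) -> pd.DataFrame:
    """Generated table rescaled to hit national aggregates exactly.

    Each pool has a disjoint set of multiplicative handles — vegetation
    density for the vegetation pool, both soil densities (and ``sd_simp``)
    for soil, population for humans, floor areas and household counts for
    buildings — and every pool is linear in its handles, so a single
    closed-form scale factor per pool forces the national total and the
    pool partitioning to the targets with no optimization.  Urban areas
    are untouched, so the national carbon density follows as
    total / area.
    """
    cfg = cfg or GeneratorConfig()
    c = constants or ModelConstants()
    fractions = fractions or CALIBRATION_FRACTIONS
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValidationError(f"target fractions must sum to 1, got {fractions}")

    table, _ = generate_provinces(cfg)
    pools = pools_table(table, c)
    current = {
        "vegetation": pools["c_veg"].sum(),
        "soil": pools["c_soil"].sum(),
        "humans": pools["c_human"].sum(),
        "buildings": pools["c_building"].sum(),
    }
    scale = {pool: total_tg * fractions[pool] / current[pool] for pool in current}

    out = table.copy()
    out["d_green"] *= scale["vegetation"]
    for col in ("d_sgreen", "d_simp", "sd_simp"):
        out[col] *= scale["soil"]
    out["pop_urban"] *= scale["humans"]
    for col in ("floor_resid", "floor_total", "n_household"):
        out[col] *= scale["buildings"]
    return out
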