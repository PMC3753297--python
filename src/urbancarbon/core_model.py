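"""Deterministic point-estimate accounting of urban organic-carbon pools.

An urban area stores organic carbon in four compartments:

* **vegetation** — the green-space fraction of the urban area times the
  vegetation carbon density of green space;
* **soil** — soil to 100 cm beneath green space and beneath impervious
  surfaces, the two cover types assumed to tile the urban area exactly;
* **humans** — urban population times average body mass times the dry-matter
  and carbon fractions of body tissue;
* **buildings** — wood in construction materials (residential and commercial
  floor area at their respective wood-use rates) plus wood in household
  furniture, converted to carbon through wood bulk density and the carbon
  fraction of dry wood.

All masses are carried internally in kg C and reported in Tg C (1 Tg =
10^9 kg); densities are kg C m^-2.  Unit conversions are centralized in
:func:`kg_to_tg` and the area/floor constants below so every caller agrees
on the same factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ModelConstants",
    "ProvinceInputs",
    "PoolBreakdown",
    "POOL_NAMES",
    "kg_to_tg",
    "compute_pools",
    "vegetation_carbon",
    "soil_carbon",
    "human_carbon",
    "building_carbon",
    "province_pools",
    "pools_table",
]

# -- units ------------------------------------------------------------------

KG_PER_TG = 1e9          # 1 Tg C = 10^9 kg C
M2_PER_KM2 = 1e6         # urban areas tabulated in km^2, densities per m^2
FLOOR_UNIT_M2 = 1e4      # floor areas tabulated in 10^4 m^2
KG_PER_TONNE = 1e3       # wood bulk density tabulated in t m^-3

POOL_NAMES = ("vegetation", "soil", "humans", "buildings")


def kg_to_tg(kg):
    """Convert a carbon mass from kg C to Tg C (scalar or array)."""
    return kg / KG_PER_TG


class ValidationError(ValueError):
    """Raised when an input record violates a model precondition.

    The message always names the offending field so tabular ingest can
    report row/column locations.
    """


# -- constants --------------------------------------------------------------


@dataclass(frozen=True)
class ModelConstants:
    """Fixed coefficients of the bookkeeping model.

    Defaults are the literature values the accounting scheme was built
    around; every field can be overridden through a YAML/JSON config
    (see :func:`urbancarbon.io.load_constants`).

    Attributes
    ----------
    weight_ave : average human body weight, kg.
    f1 : fraction of dry organic matter in the human body.
    f2 : carbon fraction of dry organic matter (body tissue and wood alike).
    f3, f5 : wood use per unit floor area of residential / commercial
        buildings, m^3 m^-2.
    f4 : average bulk density of wood, t m^-3.
    f6 : pieces per composite furniture set (literature range 10-30).
    f7, f9 : fractions of wood and steel furniture among composite
        furniture; complementary (f7 + f9 = 1).
    f8, f10 : wood use per piece of wood / steel furniture, m^3 piece^-1.
    beta : coefficient of variation assigned to inputs without a measured
        standard deviation in the Monte Carlo step.
    """

    weight_ave: float = 60.0
    f1: float = 0.3
    f2: float = 0.5
    f3: float = 0.045
    f4: float = 0.4
    f5: float = 0.055
    f6: float = 20.0
    f7: float = 0.8
    f8: float = 0.067
    f9: float = 0.2
    f10: float = 0.026
    beta: float = 0.15

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0 or (v == 0 and f.name != "beta"):
                # beta = 0 is the no-uncertainty limit; physical constants stay positive
                raise ValidationError(f"constant {f.name!r} must be finite and > 0, got {v!r}")
        for name in ("f1", "f2", "f7", "f9"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"constant {name!r} must lie in (0, 1), got {v!r}")
        if not math.isclose(self.f7 + self.f9, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"wood and steel furniture fractions must sum to 1: f7={self.f7}, f9={self.f9}"
            )

    def with_overrides(self, overrides: Mapping[str, float]) -> "ModelConstants":
        """Return a copy with the given fields replaced (validates again)."""
        known = {f.name for f in fields(self)}
        bad = set(overrides) - known
        if bad:
            raise ValidationError(f"unknown constant(s) {sorted(bad)}; known: {sorted(known)}")
        return replace(self, **overrides)


# -- province record --------------------------------------------------------

_PROVINCE_FIELDS = (
    "province_id",
    "region",
    "area_urban",
    "green_frac",
    "d_green",
    "d_sgreen",
    "d_simp",
    "sd_simp",
    "pop_urban",
    "floor_resid",
    "floor_total",
    "n_set",
    "n_household",
)


@dataclass(frozen=True)
class ProvinceInputs:
    """One province's statistical inputs to the accounting model.

    Units: ``area_urban`` km^2; ``green_frac`` a fraction in [0, 1] (a
    yearbook percentage is divided by 100 at ingest); the three carbon
    densities and ``sd_simp`` kg C m^-2; ``floor_resid``/``floor_total``
    10^4 m^2; ``pop_urban``, ``n_household`` counts; ``n_set`` composite
    furniture sets per household.
    """

    province_id: str
    region: str
    area_urban: float
    green_frac: float
    d_green: float
    d_sgreen: float
    d_simp: float
    sd_simp: float
    pop_urban: float
    floor_resid: float
    floor_total: float
    n_set: float
    n_household: float

    def __post_init__(self) -> None:
        numeric = {f: getattr(self, f) for f in _PROVINCE_FIELDS[2:]}
        for name, v in numeric.items():
            if not np.isfinite(v):
                raise ValidationError(f"{name!r} must be finite, got {v!r} (province {self.province_id})")
        if self.area_urban <= 0:
            raise ValidationError(f"'area_urban' must be > 0, got {self.area_urban!r} (province {self.province_id})")
        if not 0.0 <= self.green_frac <= 1.0:
            raise ValidationError(f"'green_frac' must lie in [0, 1], got {self.green_frac!r} (province {self.province_id})")
        for name in ("d_green", "d_sgreen", "d_simp", "sd_simp", "pop_urban",
                     "floor_resid", "floor_total", "n_set", "n_household"):
            if numeric[name] < 0:
                raise ValidationError(f"{name!r} must be >= 0, got {numeric[name]!r} (province {self.province_id})")
        if self.floor_resid > self.floor_total:
            raise ValidationError(
                f"'floor_resid' ({self.floor_resid}) exceeds 'floor_total' "
                f"({self.floor_total}) (province {self.province_id})"
            )

    @property
    def floor_commercial(self) -> float:
        """Commercial floor area, 10^4 m^2 (total minus residential)."""
        return self.floor_total - self.floor_resid

    def to_values(self) -> dict:
        """Model-variable mapping consumed by :func:`compute_pools`."""
        return {
            "area_urban": self.area_urban,
            "green_frac": self.green_frac,
            "impervious_frac": 1.0 - self.green_frac,
            "d_green": self.d_green,
            "d_sgreen": self.d_sgreen,
            "d_simp": self.d_simp,
            "pop_urban": self.pop_urban,
            "floor_resid": self.floor_resid,
            "floor_commercial": self.floor_commercial,
            "n_set": self.n_set,
            "n_household": self.n_household,
        }

    @classmethod
    def from_row(cls, row: Mapping) -> "ProvinceInputs":
        return cls(**{f: row[f] for f in _PROVINCE_FIELDS})


@dataclass(frozen=True)
class PoolBreakdown:
    """Carbon stock of the four pools for a province, region, or nation.

    ``fractions`` maps pool name to its share of ``c_total``; for an
    all-zero record the fractions are reported as 0 and ``degenerate``
    is set.
    """

    c_veg: float
    c_soil: float
    c_human: float
    c_building: float
    c_total: float
    density: float          # kg C m^-2
    fractions: dict = field(default_factory=dict)
    degenerate: bool = False

    def as_series(self) -> pd.Series:
        s = {
            "c_veg": self.c_veg,
            "c_soil": self.c_soil,
            "c_human": self.c_human,
            "c_building": self.c_building,
            "c_total": self.c_total,
            "density": self.density,
        }
        for p in POOL_NAMES:
            s[f"frac_{p}"] = self.fractions.get(p, 0.0)
        return pd.Series(s)


# -- pool arithmetic --------------------------------------------------------


def compute_pools(values: Mapping, c: ModelConstants) -> dict:
    """Evaluate the four pool equations on scalars or aligned numpy arrays.

    ``values`` must provide the eleven model variables of
    :meth:`ProvinceInputs.to_values` (``impervious_frac`` is an explicit
    entry so the Monte Carlo and sensitivity layers can decouple it from
    ``green_frac`` when their procedures require it).  Returns a dict with
    keys ``vegetation``, ``soil``, ``humans``, ``buildings``,
    ``buildings_construction``, ``buildings_furniture`` and ``total``,
    all in Tg C.
    """
    area_m2 = values["area_urban"] * M2_PER_KM2

    veg_kg = area_m2 * values["green_frac"] * values["d_green"]
    soil_kg = area_m2 * (
        values["green_frac"] * values["d_sgreen"]
        + values["impervious_frac"] * values["d_simp"]
    )
    human_kg = values["pop_urban"] * c.weight_ave * c.f1 * c.f2

    constr_m3 = (values["floor_resid"] * c.f3 + values["floor_commercial"] * c.f5) * FLOOR_UNIT_M2
    furn_m3 = values["n_set"] * values["n_household"] * c.f6 * (c.f7 * c.f8 + c.f9 * c.f10)
    constr_kg = constr_m3 * c.f4 * KG_PER_TONNE * c.f2
    furn_kg = furn_m3 * c.f4 * KG_PER_TONNE * c.f2

    pools = {
        "vegetation": kg_to_tg(veg_kg),
        "soil": kg_to_tg(soil_kg),
        "humans": kg_to_tg(human_kg),
        "buildings_construction": kg_to_tg(constr_kg),
        "buildings_furniture": kg_to_tg(furn_kg),
    }
    pools["buildings"] = pools["buildings_construction"] + pools["buildings_furniture"]
    pools["total"] = pools["vegetation"] + pools["soil"] + pools["humans"] + pools["buildings"]
    return pools


def vegetation_carbon(p: ProvinceInputs, c: ModelConstants) -> float:
    """Vegetation carbon of the province's green space, Tg C."""
    return compute_pools(p.to_values(), c)["vegetation"]


def soil_carbon(p: ProvinceInputs, c: ModelConstants) -> float:
    """Soil carbon to 100 cm beneath green space and impervious cover, Tg C."""
    return compute_pools(p.to_values(), c)["soil"]


def human_carbon(p: ProvinceInputs, c: ModelConstants) -> float:
    """Carbon held in the bodies of the urban population, Tg C."""
    return compute_pools(p.to_values(), c)["humans"]


def building_carbon(p: ProvinceInputs, c: ModelConstants) -> tuple:
    """Wood carbon in buildings: (construction, furniture, total), Tg C."""
    pools = compute_pools(p.to_values(), c)
    return (
        pools["buildings_construction"],
        pools["buildings_furniture"],
        pools["buildings"],
    )


def province_pools(p: ProvinceInputs, c: ModelConstants) -> PoolBreakdown:
    """Full pool breakdown for one province."""
    pools = compute_pools(p.to_values(), c)
    total = pools["total"]
    density = pools["total"] * KG_PER_TG / (p.area_urban * M2_PER_KM2)
    by_pool = {
        "vegetation": pools["vegetation"],
        "soil": pools["soil"],
        "humans": pools["humans"],
        "buildings": pools["buildings"],
    }
    if total > 0:
        fractions = {k: v / total for k, v in by_pool.items()}
        degenerate = False
    else:
        fractions = {k: 0.0 for k in by_pool}
        degenerate = True
    return PoolBreakdown(
        c_veg=by_pool["vegetation"],
        c_soil=by_pool["soil"],
        c_human=by_pool["humans"],
        c_building=by_pool["buildings"],
        c_total=total,
        density=density,
        fractions=fractions,
        degenerate=degenerate,
    )


def pools_table(df: pd.DataFrame, c: ModelConstants) -> pd.DataFrame:
    """Per-province pool breakdowns for a province-inputs table.

    Validates every row through :class:`ProvinceInputs` and returns a
    DataFrame keyed like the input with the columns of
    :meth:`PoolBreakdown.as_series` plus ``province_id``, ``region``,
    ``area_urban``.
    """
    rows = []
    for _, row in df.iterrows():
        p = ProvinceInputs.from_row(row)
        b = province_pools(p, c)
        s = b.as_series()
        s["province_id"] = p.province_id
        s["region"] = p.region
        s["area_urban"] = p.area_urban
        rows.append(s)
    out = pd.DataFrame(rows).reset_index(drop=True)
    lead = ["province_id", "region", "area_urban"]
    return out[lead + [col for col in out.columns if col not in lead]]
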