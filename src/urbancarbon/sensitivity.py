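"""One-at-a-time sensitivity of the national carbon total.

Each registered input variable is increased by 10% (uniformly across all
provinces for province-level fields, globally for model constants), the
national point-estimate total is recomputed, and the relative response
100 x (C' - C)/C is reported.  The point-estimate model is multilinear, so
a variable entering only as a linear factor of pools with combined share
s responds with exactly 10s percent — the reason no response can exceed
10% and the basis of the closed-form oracle used in the tests.

Two conventions worth noting:

* ``impervious_frac`` is perturbable independently of ``green_frac``: the
  baseline sets it to 1 - green_frac, the perturbation scales it by 1.1
  while leaving green_frac alone.  Perturbing ``green_frac`` instead scales
  the green fraction in both the vegetation and soil equations, with the
  impervious fraction re-derived as 1 - 1.1 x green_frac — which turns
  negative in provinces where impervious soil is carbon-denser than green
  space vegetation plus soil combined.
* ``f7`` (wood-furniture fraction) is perturbed with ``f9`` re-derived as
  its complement; ``floor_commercial`` (= floor_total - floor_resid) is
  registered instead of floor_total so the two wood-use rates have
  independent handles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_model import ModelConstants, ValidationError, compute_pools

__all__ = [
    "SensitivityResult",
    "REGISTERED_VARIABLES",
    "national_total",
    "perturb_variable",
    "sensitivity_table",
]

_PROVINCE_VARIABLES = (
    "area_urban",
    "green_frac",
    "impervious_frac",
    "d_green",
    "d_sgreen",
    "d_simp",
    "pop_urban",
    "floor_resid",
    "floor_commercial",
    "n_set",
    "n_household",
)

_CONSTANT_VARIABLES = (
    "weight_ave", "f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8", "f10",
)

#: the 21 perturbable inputs, province-level fields first
REGISTERED_VARIABLES = _PROVINCE_VARIABLES + _CONSTANT_VARIABLES


@dataclass(frozen=True)
class SensitivityResult:
    variable_name: str
    relative_response: float     # percent change of the national total
    rank: int


def _table_values(df: pd.DataFrame) -> dict:
    """Model-variable arrays for a province-inputs table."""
    values = {
        name: df[name].to_numpy(dtype=float)
        for name in ("area_urban", "green_frac", "d_green", "d_sgreen",
                     "d_simp", "pop_urban", "floor_resid", "n_set", "n_household")
    }
    values["impervious_frac"] = 1.0 - values["green_frac"]
    values["floor_commercial"] = df["floor_total"].to_numpy(dtype=float) - values["floor_resid"]
    return values


def national_total(df: pd.DataFrame, c: ModelConstants) -> float:
    """National point-estimate carbon total, Tg C (sum over provinces)."""
    return float(np.sum(compute_pools(_table_values(df), c)["total"]))


def perturb_variable(name: str, df: pd.DataFrame, c: ModelConstants, delta: float = 0.10) -> float:
    """Relative response (%) of the national total to a ``delta`` increase of one variable.

    Province fields are scaled by (1 + delta) in every province
    simultaneously; constants are scaled globally.  The baseline inputs are
    never modified.
    """
    if name not in REGISTERED_VARIABLES:
        raise ValidationError(
            f"unknown variable {name!r}; registered: {list(REGISTERED_VARIABLES)}"
        )
    baseline = national_total(df, c)
    if baseline == 0:
        raise ValidationError("baseline national total is zero; relative response undefined")

    factor = 1.0 + delta
    values = _table_values(df)
    cp = c
    if name == "green_frac":
        values["green_frac"] = values["green_frac"] * factor
        values["impervious_frac"] = 1.0 - values["green_frac"]
    elif name in _PROVINCE_VARIABLES:
        values[name] = values[name] * factor
    elif name == "f7":
        cp = replace(c, f7=c.f7 * factor, f9=1.0 - c.f7 * factor)
    else:
        cp = replace(c, **{name: getattr(c, name) * factor})
    perturbed = float(np.sum(compute_pools(values, cp)["total"]))
    return 100.0 * (perturbed - baseline) / baseline


def sensitivity_table(df: pd.DataFrame, c: ModelConstants, delta: float = 0.10) -> pd.DataFrame:
    """OAT responses of every registered variable, ranked descending.

    Returns a DataFrame with columns ``variable_name``,
    ``relative_response`` (percent) and ``rank`` (1 = largest response).
    """
    responses = {name: perturb_variable(name, df, c, delta) for name in REGISTERED_VARIABLES}
    out = (
        pd.DataFrame(
            {"variable_name": list(responses), "relative_response": list(responses.values())}
        )
        .sort_values("relative_response", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def plot_sensitivity(table: pd.DataFrame, path: str) -> None:
    """Horizontal bar chart of OAT responses (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = table.sort_values("relative_response")
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(t) + 1))
    ax.barh(t["variable_name"], t["relative_response"], color="#4878a8")
    ax.set_xlabel("response of national total to +10% in variable (%)")
    ax.axvline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
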