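"""Monte Carlo propagation of input uncertainty through the pool model.

Each province's inputs are treated as independent random variables: most
follow a normal distribution with mean equal to the tabulated value and a
coefficient of variation ``beta`` (0.15 by default); the two soil carbon
densities follow log-normal distributions, the standard empirical model
for soil organic carbon.  The log-normal is *mean-matched*: its log-scale
parameters are chosen so the arithmetic mean and SD of the distribution
equal the tabulated value and its SD exactly, which keeps the soil pool
unbiased.  The soil density beneath impervious surfaces uses its
database-derived absolute SD (``sd_simp``); the density beneath green
space, lacking a measured SD, uses ``beta`` like the other inputs.

The residential and commercial floor areas are sampled as two independent
normals (commercial = total - residential at the point estimate): the pool
equations consume exactly that pair, and sampling (residential, total)
independently would violate residential <= total in a non-negligible
fraction of draws.

Summaries report the mean of the draws and a 95% half-width of
1.96 x SD(draws) — the spread of the Monte Carlo distribution of the
stock itself, per pool and for the total.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import ModelConstants, ProvinceInputs, ValidationError, compute_pools

__all__ = [
    "DistributionSpec",
    "UncertaintyResult",
    "lognormal_params",
    "province_specs",
    "draw_inputs",
    "mc_province",
    "mc_table",
    "combine_provinces",
]

logger = logging.getLogger(__name__)

DEFAULT_N_SIMS = 10_000

#: model variables sampled per province, in draw order
SAMPLED_VARIABLES = (
    "area_urban",
    "green_frac",
    "d_green",
    "d_sgreen",
    "d_simp",
    "pop_urban",
    "floor_resid",
    "floor_commercial",
    "n_set",
    "n_household",
)

_LOGNORMAL_VARIABLES = frozenset({"d_sgreen", "d_simp"})


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling law for one input variable (same units as the variable)."""

    variable_name: str
    family: str          # "normal" | "lognormal"
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValidationError(f"unknown family {self.family!r} for {self.variable_name!r}")
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0 for {self.variable_name!r}, got {self.sd}")
        if self.family == "lognormal" and self.mean < 0:
            raise ValidationError(f"lognormal mean must be >= 0 for {self.variable_name!r}")


@dataclass(frozen=True)
class UncertaintyResult:
    """Monte Carlo draws and summaries of a province (or combination).

    ``draws`` maps pool name (plus ``"total"``) to a vector of n_sims
    samples in Tg C; ``half_width_95`` is 1.96 x SD of the total draws.
    """

    label: str
    n_sims: int
    draws: dict                  # pool -> np.ndarray, plus "total"
    mean: float
    half_width_95: float
    pool_means: dict
    pool_half_widths: dict

    def as_series(self) -> pd.Series:
        s = {"label": self.label, "n_sims": self.n_sims,
             "mean": self.mean, "half_width_95": self.half_width_95}
        for p, m in self.pool_means.items():
            s[f"mean_{p}"] = m
            s[f"half_width_95_{p}"] = self.pool_half_widths[p]
        return pd.Series(s)


# -- log-normal moment matching --------------------------------------------


def lognormal_params(target_mean: float, target_sd: float, method: str = "closed_form"):
    """Log-scale parameters of a log-normal with given arithmetic moments.

    Returns ``(mu_log, sigma_log, k)`` where ``k = mu_log - ln(target_mean)``
    is the additive log-scale correction that re-centres the distribution on
    the target mean (``k = -sigma_log**2 / 2`` in closed form).  With
    ``method="optimize"`` the same parameters are found by numerical
    moment-matching instead of the closed form, as a fidelity cross-check.
    """
    if target_mean <= 0 or not np.isfinite(target_mean):
        raise ValidationError(f"lognormal target mean must be > 0, got {target_mean!r}")
    if target_sd < 0:
        raise ValidationError(f"lognormal target sd must be >= 0, got {target_sd!r}")
    if target_sd == 0:
        return math.log(target_mean), 0.0, 0.0

    if method == "closed_form":
        sigma2 = math.log1p((target_sd / target_mean) ** 2)
        mu = math.log(target_mean) - sigma2 / 2.0
        return mu, math.sqrt(sigma2), -sigma2 / 2.0
    if method == "optimize":
        from scipy import optimize

        def moment_gap(x):
            mu, log_sigma = x
            s2 = math.exp(2 * log_sigma)
            mean = math.exp(mu + s2 / 2)
            var = (math.exp(s2) - 1) * math.exp(2 * mu + s2)
            return [mean - target_mean, var - target_sd**2]

        x0 = [math.log(target_mean), math.log(max(target_sd / target_mean, 1e-8))]
        sol = optimize.root(moment_gap, x0, tol=1e-14)
        if not sol.success:
            raise RuntimeError(f"moment matching failed to converge: {sol.message}")
        mu, log_sigma = sol.x
        sigma = math.exp(log_sigma)
        return mu, sigma, mu - math.log(target_mean)
    raise ValueError(f"unknown method {method!r}; use 'closed_form' or 'optimize'")


# -- sampling ---------------------------------------------------------------


def province_specs(p: ProvinceInputs, c: ModelConstants) -> list:
    """Distribution specs for the sampled variables of one province.

    Normal with sd = beta x mean for every variable without a measured SD;
    mean-matched log-normal for the soil densities, ``d_simp`` with its
    tabulated absolute SD.
    """
    values = p.to_values()
    specs = []
    for name in SAMPLED_VARIABLES:
        mean = values[name]
        if name == "d_simp":
            specs.append(DistributionSpec(name, "lognormal", mean, p.sd_simp))
        elif name in _LOGNORMAL_VARIABLES:
            specs.append(DistributionSpec(name, "lognormal", mean, c.beta * mean))
        else:
            specs.append(DistributionSpec(name, "normal", mean, c.beta * mean))
    return specs


def draw_inputs(specs: Sequence[DistributionSpec], n: int, seed=None, rng=None) -> pd.DataFrame:
    """``n`` independent joint draws of the spec'd variables.

    Normal draws are clipped at 0 (the quantities are physically
    non-negative; at CV 0.15 the clip probability is ~1e-11 per draw) and
    clip events are logged.  Log-normal draws are strictly positive by
    construction; a zero-mean log-normal variable degenerates to the
    constant 0.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    names = [s.variable_name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate variable names in specs: {names}")
    if rng is None:
        rng = np.random.default_rng(seed)
    cols = {}
    for s in specs:
        if s.sd == 0:
            cols[s.variable_name] = np.full(n, s.mean)
            continue
        if s.family == "normal":
            x = rng.normal(s.mean, s.sd, size=n)
            clipped = int(np.count_nonzero(x < 0))
            if clipped:
                logger.info("clipped %d/%d negative normal draws of %r at 0",
                            clipped, n, s.variable_name)
                x = np.clip(x, 0.0, None)
        else:
            if s.mean == 0:
                cols[s.variable_name] = np.zeros(n)
                continue
            mu, sigma, _ = lognormal_params(s.mean, s.sd)
            x = rng.lognormal(mu, sigma, size=n)
        cols[s.variable_name] = x
    return pd.DataFrame(cols)


def _summarize(label: str, pool_draws: dict, n: int) -> UncertaintyResult:
    total = pool_draws["total"]
    means = {k: float(np.mean(v)) for k, v in pool_draws.items() if k != "total"}
    hws = {k: 1.96 * float(np.std(v, ddof=1)) for k, v in pool_draws.items() if k != "total"}
    return UncertaintyResult(
        label=label,
        n_sims=n,
        draws=pool_draws,
        mean=float(np.mean(total)),
        half_width_95=1.96 * float(np.std(total, ddof=1)),
        pool_means=means,
        pool_half_widths=hws,
    )


def _province_rng(seed: int, province_id: str) -> np.random.Generator:
    # keyed on the province id so adding/reordering provinces leaves the
    # other provinces' substreams untouched
    return np.random.default_rng([seed, zlib.crc32(province_id.encode("utf-8"))])


def mc_province(
    p: ProvinceInputs,
    c: ModelConstants,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> UncertaintyResult:
    """Monte Carlo uncertainty of one province's carbon pools.

    Draws a joint input table from :func:`province_specs`, evaluates the
    pool equations on every draw, and summarizes each pool and the total.
    The impervious fraction tracks the sampled green fraction as
    ``1 - green_frac`` on every draw, as in the point-estimate model.
    """
    if n_sims < 2:
        raise ValidationError(f"n_sims must be >= 2 to summarize dispersion, got {n_sims}")
    if rng is None:
        rng = _province_rng(seed, p.province_id)
    table = draw_inputs(province_specs(p, c), n_sims, rng=rng)
    values = {name: table[name].to_numpy() for name in table.columns}
    values["impervious_frac"] = 1.0 - values["green_frac"]
    pools = compute_pools(values, c)
    pool_draws = {k: pools[k] for k in ("vegetation", "soil", "humans", "buildings", "total")}
    return _summarize(p.province_id, pool_draws, n_sims)


def mc_table(
    df: pd.DataFrame,
    c: ModelConstants,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> dict:
    """Per-province Monte Carlo results for a province-inputs table.

    Returns ``{province_id: UncertaintyResult}``; every province gets an
    independent substream derived from ``seed`` and its id.
    """
    results = {}
    for _, row in df.iterrows():
        p = ProvinceInputs.from_row(row)
        results[p.province_id] = mc_province(p, c, n_sims=n_sims, seed=seed)
    return results


def combine_provinces(results: Iterable[UncertaintyResult], label: str = "combined") -> UncertaintyResult:
    """Sum Monte Carlo draws index-wise across independent provinces.

    Requires equal ``n_sims``; provinces are assumed independent, so the
    per-draw totals simply add and the combined SD approaches
    sqrt(sum of squared SDs).
    """
    results = list(results)
    if not results:
        raise ValidationError("no results to combine")
    n = results[0].n_sims
    if any(r.n_sims != n for r in results):
        raise ValidationError(f"mismatched n_sims: {[r.n_sims for r in results]}")
    pool_draws = {
        k: np.sum([r.draws[k] for r in results], axis=0)
        for k in results[0].draws
    }
    return _summarize(label, pool_draws, n)
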