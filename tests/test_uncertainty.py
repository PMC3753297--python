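"""Monte Carlo machinery: moment matching, sampling, propagation, combination."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from urbancarbon import (
    DistributionSpec,
    ModelConstants,
    ProvinceInputs,
    ValidationError,
    combine_provinces,
    draw_inputs,
    lognormal_params,
    mc_province,
    mc_table,
    province_pools,
    province_specs,
)


def _veg_only_province(**overrides) -> ProvinceInputs:
    """Province whose only nonzero pool is vegetation."""
    base = dict(
        province_id="veg", region="East", area_urban=200.0, green_frac=0.3,
        d_green=1.2, d_sgreen=0.0, d_simp=0.0, sd_simp=0.0, pop_urban=0.0,
        floor_resid=0.0, floor_total=0.0, n_set=0.0, n_household=0.0,
    )
    base.update(overrides)
    return ProvinceInputs(**base)


class TestLognormalParams:
    def test_zero_sd_degenerates(self):
        mu, sigma, k = lognormal_params(3.0, 0.0)
        assert (mu, sigma, k) == (math.log(3.0), 0.0, 0.0)

    def test_unit_mean_cv_015(self):
        mu, sigma, k = lognormal_params(1.0, 0.15)
        assert sigma == pytest.approx(math.sqrt(math.log(1.0225)), rel=1e-12)
        assert k == pytest.approx(-0.5 * math.log(1.0225), rel=1e-12)
        assert mu == k  # ln(1) = 0

    @given(
        mean=st.floats(min_value=0.01, max_value=100.0),
        cv=st.floats(min_value=0.0, max_value=2.0),
    )
    def test_analytic_mean_and_sd_match_targets(self, mean, cv):
        sd = cv * mean
        mu, sigma, k = lognormal_params(mean, sd)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(mean, rel=1e-12)
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-9, abs=1e-12)
        assert k == pytest.approx(mu - math.log(mean), rel=1e-9, abs=1e-15)

    def test_optimize_mode_agrees_with_closed_form(self):
        a = lognormal_params(8.0, 2.5, method="closed_form")
        b = lognormal_params(8.0, 2.5, method="optimize")
        assert a == pytest.approx(b, rel=1e-8)

    def test_empirical_mean_converges(self):
        mu, sigma, _ = lognormal_params(6.0, 2.0)
        rng = np.random.default_rng(5)
        draws = rng.lognormal(mu, sigma, size=100_000)
        assert draws.mean() == pytest.approx(6.0, rel=0.01)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValidationError):
            lognormal_params(0.0, 1.0)
        with pytest.raises(ValidationError):
            lognormal_params(-2.0, 1.0)


class TestDrawInputs:
    def test_zero_sd_returns_point_estimates(self):
        specs = [
            DistributionSpec("a", "normal", 4.0, 0.0),
            DistributionSpec("b", "lognormal", 2.0, 0.0),
        ]
        table = draw_inputs(specs, n=1, seed=0)
        assert table.loc[0, "a"] == 4.0
        assert table.loc[0, "b"] == 2.0

    def test_same_seed_identical_tables(self):
        specs = [DistributionSpec("x", "normal", 1.0, 0.15),
                 DistributionSpec("y", "lognormal", 5.0, 1.0)]
        t1 = draw_inputs(specs, n=500, seed=42)
        t2 = draw_inputs(specs, n=500, seed=42)
        assert t1.equals(t2)

    def test_sample_means_match_spec_means(self):
        specs = [DistributionSpec("x", "normal", 10.0, 1.5),
                 DistributionSpec("y", "lognormal", 7.0, 2.1)]
        table = draw_inputs(specs, n=100_000, seed=9)
        assert table["x"].mean() == pytest.approx(10.0, rel=0.01)
        assert table["y"].mean() == pytest.approx(7.0, rel=0.01)

    def test_lognormal_draws_strictly_positive_normals_clipped(self):
        specs = [DistributionSpec("y", "lognormal", 1.0, 3.0),
                 DistributionSpec("x", "normal", 1.0, 3.0)]   # heavy clipping
        table = draw_inputs(specs, n=10_000, seed=3)
        assert (table["y"] > 0).all()
        assert (table["x"] >= 0).all()

    def test_duplicate_names_rejected(self):
        specs = [DistributionSpec("x", "normal", 1.0, 0.1)] * 2
        with pytest.raises(ValidationError, match="duplicate"):
            draw_inputs(specs, n=10, seed=0)


class TestProvinceSpecs:
    def test_families_and_sds(self, constants, demo_province):
        specs = {s.variable_name: s for s in province_specs(demo_province, constants)}
        assert specs["d_sgreen"].family == "lognormal"
        assert specs["d_simp"].family == "lognormal"
        assert specs["d_simp"].sd == demo_province.sd_simp        # measured absolute SD
        assert specs["d_sgreen"].sd == pytest.approx(0.15 * demo_province.d_sgreen)
        assert specs["area_urban"].family == "normal"
        assert specs["area_urban"].sd == pytest.approx(0.15 * demo_province.area_urban)
        assert specs["floor_commercial"].mean == pytest.approx(
            demo_province.floor_total - demo_province.floor_resid
        )


class TestMcProvince:
    def test_no_dispersion_collapses_to_point_estimate(self, demo_province):
        c = ModelConstants(beta=0.0)
        p = dataclasses.replace(demo_province, sd_simp=0.0)
        r = mc_province(p, c, n_sims=100, seed=1)
        point = province_pools(p, c)
        assert r.half_width_95 == 0.0
        assert r.mean == pytest.approx(point.c_total, rel=1e-12)

    def test_mean_close_to_point_estimate(self, constants, demo_province):
        r = mc_province(demo_province, constants, n_sims=10_000, seed=2)
        point = province_pools(demo_province, constants)
        assert r.mean == pytest.approx(point.c_total, rel=0.02)

    def test_vegetation_only_cv_matches_three_factor_product(self, constants):
        """area x green_frac x d_green, each CV 15% -> total CV ~ 26%."""
        r = mc_province(_veg_only_province(), constants, n_sims=20_000, seed=4)
        cv = (r.half_width_95 / 1.96) / r.mean
        expected = math.sqrt(1.0225**3 - 1.0)   # ~0.2628 for independent factors
        assert cv == pytest.approx(expected, rel=0.08)

    def test_seed_determinism(self, constants, demo_province):
        r1 = mc_province(demo_province, constants, n_sims=1000, seed=6)
        r2 = mc_province(demo_province, constants, n_sims=1000, seed=6)
        assert r1.mean == r2.mean
        assert r1.half_width_95 == r2.half_width_95
        assert np.array_equal(r1.draws["total"], r2.draws["total"])

    def test_total_draws_equal_summed_pool_draws(self, constants, demo_province):
        r = mc_province(demo_province, constants, n_sims=1000, seed=7)
        summed = (r.draws["vegetation"] + r.draws["soil"]
                  + r.draws["humans"] + r.draws["buildings"])
        np.testing.assert_allclose(r.draws["total"], summed, rtol=1e-12)

    def test_half_width_grows_with_beta(self, demo_province):
        lo = mc_province(demo_province, ModelConstants(beta=0.10), n_sims=4000, seed=8)
        hi = mc_province(demo_province, ModelConstants(beta=0.20), n_sims=4000, seed=8)
        assert hi.half_width_95 > lo.half_width_95

    def test_rejects_tiny_n(self, constants, demo_province):
        with pytest.raises(ValidationError, match="n_sims"):
            mc_province(demo_province, constants, n_sims=1, seed=0)


class TestCombineProvinces:
    def test_single_result_is_identity(self, constants, demo_province):
        r = mc_province(demo_province, constants, n_sims=500, seed=10)
        combined = combine_provinces([r])
        assert combined.mean == pytest.approx(r.mean, rel=1e-12)
        assert np.array_equal(combined.draws["total"], r.draws["total"])

    def test_independent_sds_add_in_quadrature(self, constants):
        p1 = _veg_only_province(province_id="a", area_urban=100.0)
        p2 = _veg_only_province(province_id="b", area_urban=300.0, d_green=0.8)
        r1 = mc_province(p1, constants, n_sims=20_000, seed=12)
        r2 = mc_province(p2, constants, n_sims=20_000, seed=12)
        combined = combine_provinces([r1, r2])
        s1, s2 = r1.half_width_95 / 1.96, r2.half_width_95 / 1.96
        expected = math.sqrt(s1**2 + s2**2)
        assert combined.half_width_95 / 1.96 == pytest.approx(expected, rel=0.03)

    def test_zero_variance_provinces_combine_to_zero_width(self, demo_province):
        c = ModelConstants(beta=0.0)
        provinces = [
            dataclasses.replace(demo_province, province_id=f"p{i}", sd_simp=0.0)
            for i in range(3)
        ]
        results = [mc_province(p, c, n_sims=50, seed=i) for i, p in enumerate(provinces)]
        assert combine_provinces(results).half_width_95 == 0.0

    def test_mismatched_n_sims_rejected(self, constants, demo_province):
        r1 = mc_province(demo_province, constants, n_sims=100, seed=0)
        r2 = mc_province(demo_province, constants, n_sims=200, seed=0)
        with pytest.raises(ValidationError, match="n_sims"):
            combine_provinces([r1, r2])


class TestSubstreams:
    def test_province_draws_unchanged_by_table_membership(self, constants, calibrated_table):
        """Each province's substream is keyed on its id, not its row position."""
        full = mc_table(calibrated_table, constants, n_sims=200, seed=3)
        subset = mc_table(calibrated_table.iloc[5:8], constants, n_sims=200, seed=3)
        for pid, r in subset.items():
            np.testing.assert_array_equal(r.draws["total"], full[pid].draws["total"])
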