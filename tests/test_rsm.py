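"""Central composite designs, quadratic surfaces, ANOVA and optimization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from whey2xanthin import rsm
from whey2xanthin.rsm import DEFAULT_FACTORS, Factor
from whey2xanthin.synthdata import gen_ccd_responses

# Published quadratic coefficients (coded units) for both responses.
BCRX_COEFFS = {
    "Intercept": 16.09,
    "yeast_extract_g_l": 2.17,
    "peptone_g_l": 1.27,
    "cheese_whey_pct_v_v": 1.34,
    "ph": 0.37,
    "yeast_extract_g_l:peptone_g_l": -0.98,
    "yeast_extract_g_l:cheese_whey_pct_v_v": -0.81,
    "yeast_extract_g_l:ph": -0.18,
    "peptone_g_l:cheese_whey_pct_v_v": -0.67,
    "peptone_g_l:ph": -0.14,
    "cheese_whey_pct_v_v:ph": 1.184e-3,
    "yeast_extract_g_l^2": -1.84,
    "peptone_g_l^2": -0.84,
    "cheese_whey_pct_v_v^2": -0.92,
    "ph^2": -1.53,
}
BIOMASS_COEFFS = {
    "Intercept": 5.18,
    "yeast_extract_g_l": 0.26,
    "peptone_g_l": 0.038,
    "cheese_whey_pct_v_v": 0.24,
    "ph": 0.081,
    "yeast_extract_g_l:peptone_g_l": -0.21,
    "yeast_extract_g_l:cheese_whey_pct_v_v": -0.14,
    "yeast_extract_g_l:ph": -0.15,
    "peptone_g_l:cheese_whey_pct_v_v": 1.969e-3,
    "peptone_g_l:ph": -0.046,
    "cheese_whey_pct_v_v:ph": 0.16,
    "yeast_extract_g_l^2": -0.51,
    "peptone_g_l^2": -0.33,
    "cheese_whey_pct_v_v^2": -0.33,
    "ph^2": -0.48,
}
OPTIMUM_ACTUAL = [11.47, 5.29, 12.00, 7.83]


def _coef_series(surface):
    names = rsm._term_names(surface.factor_names)
    return dict(zip(names, surface.coefficients))


class TestBuildCCD:
    @pytest.mark.parametrize(
        "n, n_center, expected",
        [(4, 6, 30), (2, 1, 9), (3, 6, 20)],
        ids=["four-factor", "two-factor", "three-factor"],
    )
    def test_run_count_identity(self, n, n_center, expected):
        factors = [Factor(f"f{i}", 0.0, 1.0) for i in range(n)]
        design = rsm.build_ccd(factors, n_center=n_center)
        assert design.n_runs == expected == 2**n + 2 * n + n_center

    def test_four_factor_structure(self):
        design = rsm.build_ccd(DEFAULT_FACTORS, n_center=6)
        Z = design.runs
        assert np.all(np.abs(Z[:16]) == 1)  # factorial corners
        axial = Z[16:24]
        assert np.all(np.sum(axial != 0, axis=1) == 1)
        assert set(np.abs(axial).max(axis=1)) == {2.0}  # alpha = 2 for n = 4
        assert np.all(Z[24:] == 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            rsm.build_ccd([Factor("a", 0, 1)], n_center=1)
        with pytest.raises(ValueError):
            rsm.build_ccd([Factor("a", 0, 1), Factor("b", 0, 1)], n_center=0)
        with pytest.raises(ValueError):
            Factor("a", 0, step=0.0)


class TestCoding:
    def test_center_and_axial_levels(self):
        assert np.allclose(
            rsm.code_point(DEFAULT_FACTORS, [10, 5, 10, 7.75]), [0, 0, 0, 0]
        )
        coded = rsm.code_point(DEFAULT_FACTORS, [20, 5, 10, 7.75])
        assert coded[0] == pytest.approx(2.0)

    def test_reported_optimum_codes_to_interior_point(self):
        coded = rsm.code_point(DEFAULT_FACTORS, OPTIMUM_ACTUAL)
        assert np.allclose(coded, [0.294, 0.116, 0.400, 0.1067], atol=5e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rsm.code_point(DEFAULT_FACTORS, [1.0, 2.0])

    @given(
        centers=st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        steps=st.lists(st.floats(0.1, 10), min_size=3, max_size=3),
        point=st.lists(st.floats(-100, 100), min_size=3, max_size=3),
    )
    def test_decode_code_identity(self, centers, steps, point):
        factors = [
            Factor(f"f{i}", c, s) for i, (c, s) in enumerate(zip(centers, steps))
        ]
        z = rsm.code_point(factors, point)
        assert np.allclose(rsm.decode_point(factors, z), point, atol=1e-8)


class TestFitQuadratic:
    @pytest.mark.parametrize(
        "response, expected",
        [("bcrx_mg_l", BCRX_COEFFS), ("biomass_g_l", BIOMASS_COEFFS)],
        ids=["product-yield", "biomass"],
    )
    def test_published_coefficients(self, table1, surfaces, response, expected):
        coefs = _coef_series(surfaces[response])
        for term, ref in expected.items():
            assert coefs[term] == pytest.approx(ref, abs=0.01), term

    def test_zero_noise_recovery_to_machine_precision(self, surfaces):
        truth = surfaces["bcrx_mg_l"]
        design = gen_ccd_responses([truth], noise_sd=0.0)
        refit = rsm.fit_quadratic(design, "bcrx_mg_l")
        assert np.allclose(refit.coefficients, truth.coefficients, atol=1e-9)

    def test_rank_deficient_design_raises(self):
        # drop the axial points: pure quadratic columns become confounded
        design = rsm.build_ccd(DEFAULT_FACTORS, n_center=6)
        keep = np.r_[0:16, 24:30]
        broken = rsm.Design(
            factors=design.factors, runs=design.runs[keep], n_center=6,
            responses={"y": np.ones(22)},
        )
        with pytest.raises(np.linalg.LinAlgError):
            rsm.fit_quadratic(broken, "y")

    def test_missing_response(self, table1):
        with pytest.raises(KeyError):
            rsm.fit_quadratic(table1, "nope")


class TestAnova:
    def test_published_product_yield_anova(self, table1, surfaces):
        rep = rsm.anova(table1, surfaces["bcrx_mg_l"])
        tab = rep.table
        assert tab.loc["cor total", "SS"] == pytest.approx(383.81, abs=0.01)
        assert tab.loc["residual", "SS"] == pytest.approx(4.31, abs=0.01)
        assert tab.loc["pure error", "SS"] == pytest.approx(2.11, abs=0.01)
        assert tab.loc["lack of fit", "F"] == pytest.approx(0.52, abs=0.01)
        assert tab.loc["model", "F"] == pytest.approx(94.32, rel=1e-3)
        assert rep.r2 == pytest.approx(0.9888, abs=5e-5)
        assert rep.adj_r2 == pytest.approx(0.9783, abs=5e-5)
        assert rep.pred_r2 == pytest.approx(0.9590, abs=5e-5)
        assert rep.adeq_precision == pytest.approx(34.403, rel=5e-3)

    def test_ss_and_df_bookkeeping(self, table1, surfaces):
        for surf in surfaces.values():
            rep = rsm.anova(table1, surf)
            tab = rep.table
            assert tab.loc["model", "SS"] + tab.loc["residual", "SS"] == pytest.approx(
                tab.loc["cor total", "SS"]
            )
            assert tab.loc["lack of fit", "SS"] + tab.loc[
                "pure error", "SS"
            ] == pytest.approx(tab.loc["residual", "SS"])
            assert tab.loc["model", "df"] == 14
            assert tab.loc["residual", "df"] == 15
            assert tab.loc["lack of fit", "df"] == 10
            assert tab.loc["pure error", "df"] == 5
            assert tab.loc["cor total", "df"] == 29
            assert rep.pred_r2 <= rep.adj_r2 <= rep.r2

    def test_partial_ss_identity_for_coded_columns(self, table1, surfaces):
        # linear columns have sum z² = 24, interaction columns 16 in this CCD
        surf = surfaces["bcrx_mg_l"]
        rep = rsm.anova(table1, surf)
        names = rsm._term_names(surf.factor_names)
        beta = dict(zip(names, surf.coefficients))
        for j, f in enumerate(surf.factor_names):
            assert rep.table.loc[f, "SS"] == pytest.approx(beta[f] ** 2 * 24, rel=1e-9)
        for pair, coef in surf.interaction.items():
            term = f"{pair[0]}:{pair[1]}"
            assert rep.table.loc[term, "SS"] == pytest.approx(coef**2 * 16, rel=1e-9)

    def test_no_center_replicates_warns_and_omits_purity_rows(self, surfaces):
        design = gen_ccd_responses([surfaces["bcrx_mg_l"]], n_center=1)
        surf = rsm.fit_quadratic(design, "bcrx_mg_l")
        with pytest.warns(UserWarning, match="pure-error"):
            rep = rsm.anova(design, surf)
        assert "pure error" not in rep.table.index


class TestStandardizedEffects:
    def test_ranking_and_significance(self, table1, surfaces):
        effects, t_crit = rsm.standardized_effects(table1, surfaces["bcrx_mg_l"])
        linear = effects[
            [f.name for f in table1.factors]
        ].sort_values(ascending=False)
        assert linear.index[0] == "yeast_extract_g_l"
        assert linear.index[1] == "cheese_whey_pct_v_v"
        assert effects["cheese_whey_pct_v_v:ph"] < t_crit  # CD not significant

    def test_t_squared_equals_partial_f(self, table1, surfaces):
        surf = surfaces["bcrx_mg_l"]
        rep = rsm.anova(table1, surf)
        for term in rep.standardized_effects.index:
            assert rep.standardized_effects[term] ** 2 == pytest.approx(
                rep.table.loc[term, "F"], rel=1e-9
            )


class TestPredict:
    def test_center_point_gives_intercept(self, surfaces):
        for surf in surfaces.values():
            assert rsm.predict(surf, np.zeros(4)) == pytest.approx(surf.intercept)

    def test_published_optimum_predictions(self, table1, surfaces):
        z = rsm.code_point(table1.factors, OPTIMUM_ACTUAL)
        assert rsm.predict(surfaces["bcrx_mg_l"], z) == pytest.approx(16.95, abs=0.01)
        assert rsm.predict(surfaces["biomass_g_l"], z) == pytest.approx(5.23, abs=0.01)


class TestOptimize:
    def test_analytic_sphere_maximum(self):
        beta = np.zeros(15)
        beta[0] = 1.0
        beta[11:15] = -1.0  # y = 1 - sum z^2
        surf = rsm.QuadraticSurface.from_coefficients(
            "y", [f.name for f in DEFAULT_FACTORS], beta
        )
        res = rsm.optimize([surf], mode="single")
        assert np.allclose(res.coded_point, 0, atol=1e-6)
        assert res.predicted["y"] == pytest.approx(1.0, abs=1e-9)

    def test_interior_optimum_matches_stationary_point(self):
        # independent oracle: solve the gradient system of the polynomial
        rng = np.random.default_rng(7)
        A = rng.normal(size=(4, 4))
        Q = -(A @ A.T) - 4 * np.eye(4)  # negative definite quadratic part
        b = rng.normal(size=4) * 0.5
        z_star = np.linalg.solve(-2 * Q, b)
        assert np.all(np.abs(z_star) < 1)  # interior of the coded box
        names = [f.name for f in DEFAULT_FACTORS]
        beta = np.concatenate(
            [[0.0], b,
             [Q[i, j] * 2 for i in range(4) for j in range(i + 1, 4)],
             np.diag(Q)]
        )
        surf = rsm.QuadraticSurface.from_coefficients("y", names, beta)
        res = rsm.optimize([surf], mode="single")
        assert np.allclose(res.coded_point, z_star, atol=1e-5)

    def test_desirability_recovers_published_optimum(self, table1, surfaces):
        res = rsm.optimize(list(surfaces.values()), factors=table1.factors)
        assert np.allclose(res.coded_point, [0.29, 0.12, 0.40, 0.11], atol=0.05)
        assert np.allclose(res.actual_point, OPTIMUM_ACTUAL, atol=[0.25, 0.07, 0.25, 0.03])
        assert res.predicted["bcrx_mg_l"] == pytest.approx(16.95, abs=0.05)
        assert res.predicted["biomass_g_l"] == pytest.approx(5.23, abs=0.05)
        assert 0 < res.desirability <= 1

    def test_empty_surface_list(self):
        with pytest.raises(ValueError):
            rsm.optimize([])
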