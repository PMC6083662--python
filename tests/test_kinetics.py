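"""Closed-form batch kinetics, their ODE/quadrature oracles, and fitting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from whey2xanthin import kinetics as kin
from whey2xanthin.synthdata import DEFAULT_TIME_GRID, gen_timecourse

CONDITIONS = [3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0]


def growth_strategy():
    return st.tuples(
        st.floats(0.005, 0.1), st.floats(1.0, 8.0), st.floats(0.02, 0.5)
    ).map(lambda t: kin.GrowthParams(t[0], t[1], t[2]))


class TestClosedForms:
    def test_boundary_conditions(self, table3):
        for sets in table3.values():
            g, s, p = sets["growth"], sets["substrate"], sets["product"]
            assert kin.logistic_X(0.0, g) == pytest.approx(g.X0, rel=1e-12)
            assert kin.substrate_SL(0.0, g, s) == pytest.approx(s.SL0, rel=1e-12)
            assert kin.product_P(0.0, g, p) == 0.0

    def test_logistic_asymptote(self, table3):
        g = table3[12.0]["growth"]
        t_large = 25.0 / g.mu
        assert kin.logistic_X(t_large, g) == pytest.approx(g.Xm, rel=1e-6)

    def test_twelve_percent_reference_values(self, table3):
        # frozen from independent ODE/quadrature evaluation of the rate laws
        sets = table3[12.0]
        assert kin.logistic_X(20.0, sets["growth"]) == pytest.approx(0.5773, abs=5e-4)
        assert kin.substrate_SL(120.0, sets["growth"], sets["substrate"]) \
            == pytest.approx(2.390, abs=2e-3)
        assert kin.product_P(120.0, sets["growth"], sets["product"]) \
            == pytest.approx(18.84, abs=0.01)

    def test_substrate_no_maintenance_mass_balance(self, table3):
        g = table3[12.0]["growth"]
        s = kin.SubstrateParams(SL0=4.22, Y_XS=16.95, mC=0.0)
        t_large = 30.0 / g.mu
        expected = s.SL0 - (g.Xm - g.X0) / s.Y_XS
        assert kin.substrate_SL(t_large, g, s) == pytest.approx(expected, rel=1e-6)

    def test_product_zero_coefficients(self, table3):
        g = table3[12.0]["growth"]
        p = kin.ProductParams(alpha=0.0, beta=0.0, delta_t=2.0)
        assert np.all(kin.product_P(DEFAULT_TIME_GRID, g, p) == 0.0)

    def test_negative_lactose_flagged_not_clipped(self, table3):
        g = table3[12.0]["growth"]
        s = kin.SubstrateParams(SL0=0.5, Y_XS=16.95, mC=0.05)
        vals, neg = kin.substrate_SL(np.array([0.0, 500.0]), g, s,
                                     warn_negative=True)
        assert vals[1] < 0 and neg[1] and not neg[0]

    @pytest.mark.parametrize("condition", CONDITIONS)
    def test_logistic_matches_ode_oracle(self, table3, condition):
        g = table3[condition]["growth"]
        t_eval = DEFAULT_TIME_GRID
        sol = solve_ivp(
            lambda t, x: g.mu * x[0] * (1 - x[0] / g.Xm), (0, 120), [g.X0],
            t_eval=t_eval, rtol=1e-11, atol=1e-13,
        )
        assert np.max(np.abs(sol.y[0] - kin.logistic_X(t_eval, g))) < 1e-6

    @pytest.mark.parametrize("condition", [3.0, 12.0, 21.0])
    def test_substrate_matches_quadrature_oracle(self, table3, condition):
        g, s = table3[condition]["growth"], table3[condition]["substrate"]
        for t_end in (24.0, 72.0, 120.0):
            integral, _ = quad(lambda u: kin.logistic_X(u, g), 0, t_end, limit=200)
            oracle = s.SL0 - (kin.logistic_X(t_end, g) - g.X0) / s.Y_XS \
                - s.mC * integral
            assert kin.substrate_SL(t_end, g, s) == pytest.approx(oracle, abs=1e-5)

    @pytest.mark.parametrize("condition", [3.0, 12.0, 21.0])
    def test_product_matches_quadrature_oracle(self, table3, condition):
        g, p = table3[condition]["growth"], table3[condition]["product"]
        for t_end in (24.0, 72.0, 120.0):
            shifted = lambda u: kin.logistic_X(u - p.delta_t, g)  # noqa: E731
            integral, _ = quad(shifted, 0, t_end, limit=200)
            oracle = p.alpha * (shifted(t_end) - shifted(0.0)) + p.beta * integral
            assert kin.product_P(t_end, g, p) == pytest.approx(oracle, abs=1e-5)

    @given(g=growth_strategy(), dt=st.floats(0, 12))
    def test_monotonicity(self, g, dt):
        t = np.linspace(0, 120, 61)
        X = kin.logistic_X(t, g)
        assert np.all(np.diff(X) >= -1e-12)
        s = kin.SubstrateParams(5.0, 10.0, 0.003)
        SL = kin.substrate_SL(t, g, s)
        assert np.all(np.diff(SL) <= 1e-12)
        p = kin.ProductParams(1.5, 0.02, dt)
        P = kin.product_P(t, g, p)
        assert np.all(np.diff(P) >= -1e-12)
        assert P[0] == 0.0


class TestGoodness:
    def test_hand_arithmetic_oracle(self):
        q = kin.goodness([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], n_params=1)
        assert q.SS == pytest.approx(1.0)
        assert q.Syx == pytest.approx(np.sqrt(1.0 / 2.0))
        assert q.MSEpct == pytest.approx(100.0 / 3.0)
        assert q.n == 3 and q.df == 2

    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        q = kin.goodness(y, y, n_params=2)
        assert q.SS == 0.0 and q.r2 == 1.0 and q.MSEpct == 0.0

    def test_identities(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        f = y + rng.normal(scale=0.3, size=30)
        q = kin.goodness(y, f, n_params=3)
        assert q.Syx**2 == pytest.approx(q.SS / q.df, rel=1e-12)
        assert q.MSEpct == pytest.approx(100 * q.SS / q.n, rel=1e-12)
        assert q.r2 == pytest.approx(
            1 - q.SS / ((y - y.mean()) ** 2).sum(), rel=1e-12
        )
        assert q.sigma == pytest.approx(np.std(y, ddof=1), rel=1e-12)

    def test_insufficient_df(self):
        with pytest.raises(ValueError):
            kin.goodness([1.0, 2.0], [1.0, 2.0], n_params=2)


class TestFitting:
    @pytest.mark.parametrize("condition", [6.0, 12.0])
    def test_noise_free_roundtrip(self, table3, condition):
        sets = table3[condition]
        tc = gen_timecourse(sets["growth"], sets["substrate"], sets["product"],
                            noise_sd={}, seed=0, condition=condition)
        g, gq = kin.fit_growth(tc)
        assert g.mu == pytest.approx(sets["growth"].mu, rel=1e-3)
        assert g.Xm == pytest.approx(sets["growth"].Xm, rel=1e-3)
        assert g.X0 == pytest.approx(sets["growth"].X0, rel=5e-3)
        assert gq.SS < 1e-12
        s, _ = kin.fit_substrate(tc, g)
        assert s.Y_XS == pytest.approx(sets["substrate"].Y_XS, rel=5e-3)
        assert s.mC == pytest.approx(sets["substrate"].mC, rel=5e-3)
        p, _ = kin.fit_product(tc, g)
        assert p.alpha == pytest.approx(sets["product"].alpha, rel=5e-3)
        assert p.delta_t == pytest.approx(sets["product"].delta_t, rel=5e-3)

    def test_constant_biomass_unidentifiable(self):
        tc = kin.TimeCourse(t=np.arange(10.0), X=np.full(10, 2.0))
        with pytest.raises(kin.FitError):
            kin.fit_growth(tc)

    def test_too_few_points(self):
        tc = kin.TimeCourse(t=np.array([0.0, 1.0]), X=np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            kin.fit_growth(tc)

    def test_pure_yield_identity_with_fixed_zero_maintenance(self, table3):
        g = table3[12.0]["growth"]
        s_true = kin.SubstrateParams(SL0=4.22, Y_XS=16.95, mC=0.0)
        tc = gen_timecourse(g, s_true, None, noise_sd={}, seed=0,
                            t_lactose=DEFAULT_TIME_GRID)
        s_fit, _ = kin.fit_substrate(tc, g)
        assert s_fit.mC == pytest.approx(0.0, abs=1e-6)
        # mass-balance identity: Y = (Xm - X0) / (SL0 - SL_inf)
        sl_inf = s_true.SL0 - (g.Xm - g.X0) / s_true.Y_XS
        assert s_fit.Y_XS == pytest.approx(
            (g.Xm - g.X0) / (s_true.SL0 - sl_inf), rel=1e-3
        )

    def test_growth_associated_limit(self, table3):
        g = table3[12.0]["growth"]
        p_true = kin.ProductParams(alpha=1.5, beta=0.0, delta_t=0.0)
        tc = gen_timecourse(g, None, p_true, noise_sd={}, seed=0)
        p_fit, _ = kin.fit_product(tc, g)
        assert p_fit.beta == pytest.approx(0.0, abs=1e-5)
        dP = kin.product_P(120.0, g, p_true)
        dX = kin.logistic_X(120.0, g) - g.X0
        assert p_fit.alpha == pytest.approx(dP / dX, rel=1e-3)

    def test_noisy_growth_recovery_is_nearly_unbiased(self, table3):
        g_true = table3[12.0]["growth"]
        mus = []
        for seed in range(10):
            tc = gen_timecourse(g_true, None, None, noise_sd={"X": 0.1},
                                seed=seed)
            g, _ = kin.fit_growth(tc, n_starts=8, seed=seed)
            mus.append(g.mu)
        assert np.mean(mus) == pytest.approx(g_true.mu, rel=0.05)
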