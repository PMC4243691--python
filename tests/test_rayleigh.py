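"""Closed-system Rayleigh relations and fractionation-factor estimators."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import triplesulfur as ts
from triplesulfur import FractionationFactor, IsotopeComposition
from triplesulfur.rayleigh import (
    distill_pools,
    fit_epsilon34,
    fit_lambda33,
    product_delta,
    propagate_lambda_error,
    reactant_delta,
)


def _ode_reactant(delta0, f, alpha):
    """Numerically integrate the instantaneous-distillation rate law.

    d x_R / x_R = (alpha - 1) dR / R with x = delta + 1000; the analytic
    solution is the closed-system power law, so the integral provides an
    independent oracle for the implementation.
    """
    sol = solve_ivp(
        lambda u, x: (alpha - 1.0) * x / u,
        (1.0, f),
        [delta0 + 1000.0],
        rtol=1e-12,
        atol=1e-12,
        dense_output=True,
    )
    return sol.y[0, -1] - 1000.0


def _ode_product(delta0, f, alpha, n=200_000):
    """Accumulated product by direct summation of instantaneous parcels."""
    us = np.linspace(1.0, f, n)
    x_r = (delta0 + 1000.0) * us ** (alpha - 1.0)
    inst = alpha * x_r
    # integrate inst over consumed reactant (-du), then average
    total = np.trapezoid(inst[::-1], us[::-1])
    return total / (1.0 - f) - 1000.0


class TestReactantDelta:
    def test_no_consumption_returns_initial(self):
        assert reactant_delta(4.2, 1.0, FractionationFactor(0.97)) == pytest.approx(4.2)

    def test_no_fractionation_returns_initial(self):
        assert reactant_delta(4.2, 0.3, FractionationFactor(1.0)) == pytest.approx(4.2)

    def test_matches_distillation_ode_oracle(self):
        alpha = 1.0 - 25.0 / 1000.0
        got = reactant_delta(0.0, 0.5, alpha)
        assert got == pytest.approx(_ode_reactant(0.0, 0.5, alpha), abs=1e-6)

    def test_f_out_of_range_raises(self):
        with pytest.raises(ValueError):
            reactant_delta(0.0, 0.0, FractionationFactor(0.99))
        with pytest.raises(ValueError):
            reactant_delta(0.0, -0.2, FractionationFactor(0.99))

    def test_minor_isotope_uses_lambda_exponent(self):
        # λ relates instantaneous product to reactant: the pairwise exponent
        # between accumulated product and residual reactant recovers the
        # nominal λ to better than 0.001 at study-scale fractionations
        ff = FractionationFactor.from_epsilon(-7.12, 0.512)
        assert ff.alpha(33) == pytest.approx(ff.alpha34**0.512, abs=1e-15)
        for f in (0.95, 0.854, 0.6):
            dr = IsotopeComposition(
                reactant_delta(0.0, f, ff, 34), reactant_delta(0.0, f, ff, 33)
            )
            dp = IsotopeComposition(
                product_delta(0.0, f, ff, 34), product_delta(0.0, f, ff, 33)
            )
            assert ts.lambda_between(dp, dr) == pytest.approx(0.512, abs=0.001)


class TestProductDelta:
    def test_limit_f_to_1_is_instantaneous_product(self):
        alpha = 0.995
        inst = 1000.0 * (alpha * (1.0 + 3.0 / 1000.0) - 1.0)
        assert product_delta(3.0, 1.0 - 1e-8, alpha) == pytest.approx(inst, abs=1e-5)

    def test_matches_ode_oracle(self):
        alpha = 1.0 - 7.12 / 1000.0
        got = product_delta(0.0, 0.854, alpha)
        assert got == pytest.approx(_ode_product(0.0, 0.854, alpha), abs=1e-6)

    def test_zero_product_raises(self):
        with pytest.raises(ValueError):
            product_delta(0.0, 1.0, 0.99)

    def test_conservation_identity_with_mix(self):
        # residual reactant plus accumulated product reconstitute the
        # initial inventory exactly, in ratio space, on a random grid
        rng = np.random.default_rng(7)
        for _ in range(25):
            f = rng.uniform(0.05, 0.999)
            eps = rng.uniform(-60.0, 15.0)
            lam = rng.uniform(0.50, 0.52)
            d0 = rng.uniform(-30.0, 30.0)
            cap0 = rng.uniform(-0.1, 0.1)
            r0 = ts.SulfurPool(
                "sulfate", 20.0, None, IsotopeComposition.from_capdelta(d0, cap0)
            )
            state = distill_pools(r0, f, FractionationFactor.from_epsilon(eps, lam))
            back = ts.mix([state.reactant, state.product])
            assert back.comp.delta34 == pytest.approx(d0, abs=1e-9)
            assert back.comp.delta33 == pytest.approx(r0.comp.delta33, abs=1e-9)


class TestFitEpsilon34:
    def test_mean_of_table1_lactate_block(self, tables):
        ff = ts.epsilon_from_printed(tables["sulfate_lactate"])
        assert ff.epsilon34 == pytest.approx(-4.25, abs=0.01)
        assert ff.sd_epsilon34 == pytest.approx(0.44, abs=0.01)

    def test_noiseless_self_consistency_both_roles(self):
        truth = FractionationFactor.from_epsilon(-10.0)
        f = np.array([0.95, 0.8, 0.6, 0.4])
        d_r = [reactant_delta(0.0, fi, truth) for fi in f]
        d_p = [product_delta(0.0, fi, truth) for fi in f]
        for role, series in (("reactant", d_r), ("product", d_p)):
            ff = fit_epsilon34(f, series, role=role)
            assert ff.epsilon34 == pytest.approx(-10.0, abs=1e-9)
        ff = fit_epsilon34(f, d_p, role="paired", delta_reactant=d_r)
        assert ff.epsilon34 == pytest.approx(-10.0, abs=1e-7)

    def test_noisy_mean_within_two_standard_errors(self):
        rng = np.random.default_rng(11)
        truth = FractionationFactor.from_epsilon(-8.0)
        f = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        means = []
        for _ in range(200):
            d = [reactant_delta(0.0, fi, truth) + rng.normal(0, 0.2) for fi in f]
            means.append(fit_epsilon34(f, d, role="reactant").epsilon34)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) + 8.0) < 2 * se + 1e-3

    def test_points_below_consumption_threshold_are_excluded(self):
        truth = FractionationFactor.from_epsilon(-10.0)
        f = [0.999, 0.5]  # first point: 0.1% consumed, ill-conditioned
        d = [reactant_delta(0.0, fi, truth) + (5.0 if fi > 0.99 else 0.0) for fi in f]
        ff = fit_epsilon34(f, d, role="reactant")
        assert ff.epsilon34 == pytest.approx(-10.0, abs=1e-9)
        assert ff.sd_epsilon34 is None  # single usable point

    def test_all_points_unconsumed_raises(self):
        with pytest.raises(ValueError):
            fit_epsilon34([1.0, 0.999], [0.0, 0.1], role="reactant")


class TestFitLambda33:
    def test_sulfate_formate_pair(self):
        a = IsotopeComposition.from_capdelta(1.76, -0.01)
        b = IsotopeComposition.from_capdelta(-5.15, 0.016)
        ff = fit_lambda33(a, b)
        assert ff.lambda33 == pytest.approx(0.511, abs=0.001)

    def test_constructed_exponent_recovery(self):
        lam = 0.5100
        a34, a33 = 0.992, 0.992**lam
        a = IsotopeComposition(0.0, 0.0)
        b = IsotopeComposition(1000 * (1 / a34 - 1), 1000 * (1 / a33 - 1))
        assert fit_lambda33(b, a).lambda33 == pytest.approx(lam, abs=1e-12)

    def test_monte_carlo_sd_matches_delta_method(self):
        a = IsotopeComposition.from_capdelta(0.27, -0.02)
        b = IsotopeComposition.from_capdelta(-3.95, 0.008)
        sd_mc = propagate_lambda_error(a, b, 0.2, 0.01, n_draws=40_000, seed=3)

        # independent first-order (delta-method) propagation
        def lam_of(d34a, capa, d34b, capb):
            aa = IsotopeComposition.from_capdelta(d34a, capa)
            bb = IsotopeComposition.from_capdelta(d34b, capb)
            return ts.lambda_between(aa, bb)

        x0 = (a.delta34, a.capdelta33, b.delta34, b.capdelta33)
        sig = (0.2, 0.01, 0.2, 0.01)
        var = 0.0
        for i in range(4):
            h = 1e-6
            xp = list(x0)
            xp[i] += h
            xm = list(x0)
            xm[i] -= h
            grad = (lam_of(*xp) - lam_of(*xm)) / (2 * h)
            var += (grad * sig[i]) ** 2
        assert sd_mc == pytest.approx(np.sqrt(var), rel=0.2)

    def test_below_separation_tolerance_raises(self):
        a = IsotopeComposition.from_capdelta(0.01, 0.0)
        b = IsotopeComposition.from_capdelta(0.0, 0.01)
        with pytest.raises(ValueError):
            fit_lambda33(a, b)


class TestPropagateLambdaError:
    def test_zero_sigma_gives_zero_sd(self):
        a = IsotopeComposition.from_capdelta(2.0, 0.01)
        b = IsotopeComposition.from_capdelta(-6.0, 0.02)
        assert propagate_lambda_error(a, b, 0.0, 0.0) == 0.0

    def test_sd_shrinks_as_separation_grows(self):
        # lambda is poorly resolved at small 34-epsilon; the uncertainty
        # must fall strictly as the pools separate, at fixed measurement sigma
        sds = []
        for eps in (2.0, 5.0, 10.0, 20.0, 40.0):
            a = IsotopeComposition.from_capdelta(0.0, 0.0)
            b = IsotopeComposition.from_capdelta(-eps, 0.01)
            sds.append(propagate_lambda_error(a, b, 0.2, 0.01, n_draws=20_000, seed=5))
        assert all(x > y for x, y in zip(sds, sds[1:]))

    def test_sd_stable_between_1e4_and_1e5_draws(self):
        a = IsotopeComposition.from_capdelta(1.76, -0.01)
        b = IsotopeComposition.from_capdelta(-5.15, 0.016)
        s1 = propagate_lambda_error(a, b, 0.2, 0.01, n_draws=10_000, seed=9)
        s2 = propagate_lambda_error(a, b, 0.2, 0.01, n_draws=100_000, seed=10)
        assert s1 == pytest.approx(s2, rel=0.05)

    def test_invalid_draw_count_raises(self):
        a = IsotopeComposition.from_capdelta(1.0, 0.0)
        with pytest.raises(ValueError):
            propagate_lambda_error(a, a, 0.1, 0.01, n_draws=0)
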