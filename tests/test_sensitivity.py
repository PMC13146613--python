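"""Confounding-bias formulas, partial R^2 and the Austen plot."""

import numpy as np
import pandas as pd
import pytest

import camnet as cm
from camnet.sensitivity import BiasUnattainableError, trigamma_partial_r2


@pytest.fixture
def simulated_inputs():
    """Binary confounded treatment/outcome with one observed covariate."""
    rng = np.random.default_rng(0)
    n = 3000
    x = rng.integers(0, 2, n)
    t = (rng.random(n) < 0.3 + 0.4 * x).astype(int)
    y = (rng.random(n) < 0.2 + 0.3 * t + 0.2 * x).astype(float)
    return cm.estimate_nuisance(t, y, pd.DataFrame({"x": x}))


class TestBiasFormula:
    def test_zero_delta_zero_bias(self):
        g = np.random.default_rng(1).uniform(0.1, 0.9, 500)
        assert cm.confounding_bias(g, 0.3, 0.0) == 0.0

    def test_digamma_recurrence_closed_form(self):
        # at g = 1/2, alpha = 1/2 the bracket collapses to 4 via
        # psi(x+1) = psi(x) + 1/x
        g = np.full(100, 0.5)
        assert cm.confounding_bias(g, 0.5, 0.1) == pytest.approx(0.4, abs=1e-12)

    def test_linear_in_delta(self):
        g = np.random.default_rng(2).uniform(0.05, 0.95, 300)
        b1 = cm.confounding_bias(g, 0.4, 0.1)
        b2 = cm.confounding_bias(g, 0.4, 0.2)
        assert b2 == pytest.approx(2 * b1, rel=1e-12)

    def test_bias_vanishes_as_alpha_to_zero(self):
        g = np.full(50, 0.5)
        vals = [cm.confounding_bias(g, a, 0.1) for a in (1e-2, 1e-4, 1e-6)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-5

    def test_constant_g_bracket_matches_elementary_form(self):
        # psi recurrence: bracket = 1/(g m) + 1/((1-g) m)
        for g0, a in [(0.3, 0.25), (0.7, 0.6), (0.5, 0.9)]:
            m = 1 / a - 1
            want = (1 / (g0 * m) + 1 / ((1 - g0) * m))
            got = cm.confounding_bias(np.full(10, g0), a, 1.0)
            assert got == pytest.approx(want, rel=1e-12)

    def test_alpha_domain_checked(self):
        with pytest.raises(ValueError):
            cm.confounding_bias(np.full(5, 0.5), 1.5, 0.1)


class TestDeltaInversion:
    def test_inverts_bias_exactly(self):
        g = np.random.default_rng(3).uniform(0.1, 0.9, 200)
        for a in (0.1, 0.5, 0.9):
            d = cm.delta_for_bias(g, a, 0.1)
            assert cm.confounding_bias(g, a, d) == pytest.approx(0.1, abs=1e-12)

    def test_half_and_double(self):
        g = np.full(20, 0.5)
        assert cm.delta_for_bias(g, 0.5, 0.4) == pytest.approx(0.1, abs=1e-12)
        assert cm.delta_for_bias(g, 0.5, 0.8) == pytest.approx(0.2, abs=1e-12)

    def test_degenerate_bracket_flagged(self):
        g = np.full(5, 0.5)
        with pytest.raises(BiasUnattainableError):
            # alpha ~ 1 - eps drives m -> 0 where digamma overflows at 0
            cm.delta_for_bias(g, 1e-300, 0.1)


class TestPartialR2:
    def test_zero_delta_zero_r2(self, simulated_inputs):
        assert cm.partial_r2(0.0, simulated_inputs.g, 0.4, simulated_inputs) == 0.0

    def test_range_clipped(self, simulated_inputs):
        r = cm.partial_r2(5.0, simulated_inputs.g, 0.4, simulated_inputs)
        assert 0.0 <= r <= 1.0

    def test_monte_carlo_matches_trigamma_oracle(self, simulated_inputs):
        inp = simulated_inputs
        for a in (0.2, 0.5, 0.8):
            d = cm.delta_for_bias(inp.g, a, 0.1)
            mc = cm.partial_r2(d, inp.g, a, inp, n_draws=4000, seed=1)
            cf = trigamma_partial_r2(d, inp.g, a, inp)
            assert mc == pytest.approx(cf, rel=0.06, abs=5e-4)

    def test_seed_reproducible_and_stable(self, simulated_inputs):
        inp = simulated_inputs
        a = cm.partial_r2(0.2, inp.g, 0.4, inp, n_draws=1000, seed=7)
        b = cm.partial_r2(0.2, inp.g, 0.4, inp, n_draws=1000, seed=7)
        assert a == b
        big = cm.partial_r2(0.2, inp.g, 0.4, inp, n_draws=10000, seed=8)
        assert a == pytest.approx(big, rel=0.1)

    def test_degenerate_outcome_rejected(self):
        n = 100
        t = np.array([0, 1] * 50)
        y = t.astype(float)  # Q fits exactly at prior 0
        X = pd.DataFrame({"x": np.zeros(n, int)})
        inp = cm.estimate_nuisance(t, y, X, smoothing=0.0)
        with pytest.raises(ValueError):
            cm.partial_r2(0.1, inp.g, 0.4, inp)


class TestCovariateInfluence:
    def test_independent_covariate_near_origin(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n)
        t = (rng.random(n) < 0.3 + 0.4 * x).astype(int)
        y = (rng.random(n) < 0.2 + 0.4 * t).astype(float)
        inp = cm.estimate_nuisance(t, y, pd.DataFrame({"x": x, "z": z}))
        az, rz = cm.covariate_influence(inp, "z")
        assert az < 0.02 and rz < 0.02

    def test_duplicated_covariate_symmetric(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.integers(0, 2, n)
        t = (rng.random(n) < 0.3 + 0.4 * x).astype(int)
        y = (rng.random(n) < 0.2 + 0.3 * t + 0.2 * x).astype(float)
        inp = cm.estimate_nuisance(t, y, pd.DataFrame({"a": x, "b": x.copy()}))
        assert cm.covariate_influence(inp, "a") == cm.covariate_influence(inp, "b")

    def test_graded_strength_orders_points(self):
        rng = np.random.default_rng(7)
        n = 6000
        strong = rng.integers(0, 2, n)
        weak = rng.integers(0, 2, n)
        t = (rng.random(n) < 0.2 + 0.55 * strong + 0.1 * weak).astype(int)
        y = (rng.random(n) < 0.15 + 0.25 * t + 0.4 * strong + 0.05 * weak).astype(float)
        inp = cm.estimate_nuisance(t, y, pd.DataFrame({"s": strong, "w": weak}))
        a_s, r_s = cm.covariate_influence(inp, "s")
        a_w, r_w = cm.covariate_influence(inp, "w")
        assert a_s > a_w and r_s > r_w

    def test_unknown_covariate(self, simulated_inputs):
        with pytest.raises(KeyError):
            cm.covariate_influence(simulated_inputs, "nope")


class TestAustenPlot:
    def test_curve_monotone_and_noise_covariates_robust(self, tmp_path):
        rng = np.random.default_rng(8)
        n = 3000
        z1 = rng.integers(0, 2, n)
        z2 = rng.integers(0, 2, n)
        t = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.3 + 0.35 * t).astype(float)
        inp = cm.estimate_nuisance(t, y, pd.DataFrame({"z1": z1, "z2": z2}))
        out = tmp_path / "austen.png"
        curve = cm.austen_plot(
            inp, bias_level=0.1, alphas=np.linspace(0.05, 0.95, 19),
            n_draws=400, seed=3, plot_path=out,
        )
        r2 = curve.r2_curve
        ok = ~np.isnan(r2)
        vals = r2[ok]
        # non-increasing up to Monte-Carlo jitter in the variance estimates
        assert all(a >= b - 1e-3 for a, b in zip(vals, vals[1:]))
        assert curve.robust
        assert out.exists()

    def test_planted_confounder_breaks_robustness(self):
        rng = np.random.default_rng(9)
        n = 6000
        u = rng.integers(0, 2, n)  # dominant observed "confounder"
        t = (rng.random(n) < 0.12 + 0.75 * u).astype(int)
        y = (rng.random(n) < 0.1 + 0.08 * t + 0.7 * u).astype(float)
        inp = cm.estimate_nuisance(t, y, pd.DataFrame({"u": u}))
        curve = cm.austen_plot(
            inp, bias_level=0.02, alphas=np.linspace(0.05, 0.95, 19),
            n_draws=400, seed=4,
        )
        assert not curve.robust
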