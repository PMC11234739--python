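import math

import numpy as np
import pytest
from scipy import stats as sps

import lrvalidate as lv
from lrvalidate.intervals import IntervalSpec, reliability_summary

SPEC = IntervalSpec(alpha=0.05)


def centered_identity_trace(n):
    return n - 1  # tr(S I S) = tr(S)


class TestVarBias:
    def test_closed_forms(self):
        C = np.array([[1.0, 0.2, 0.1], [0.2, 0.9, 0.0], [0.1, 0.0, 1.1]])
        assert lv.var_bias_analytical(C, C, 3) == 0.0
        n = 4
        assert lv.var_bias_analytical(np.eye(n), np.zeros((n, n)), n) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            lv.var_bias_analytical(np.eye(3), np.eye(4), 3)

    def test_approx_arithmetic_and_diagonal_equivalence(self):
        s = reliability_summary([0.4] * 100, [0.6] * 100)
        assert lv.var_bias_approx(s, 1.0, 100) == pytest.approx(0.002)
        s0 = reliability_summary([0.3, 0.5], [0.3, 0.5])
        assert lv.var_bias_approx(s0, 1.0, 2) == 0.0
        # with diagonal C-matrices built from reliabilities the two routes agree
        rng = np.random.default_rng(1)
        rel_p = rng.uniform(0.2, 0.6, size=6)
        rel_w = rel_p + rng.uniform(0.0, 0.3, size=6)
        sigma_g2 = 1.3
        Cp = np.diag(sigma_g2 * (1 - rel_p))
        Cw = np.diag(sigma_g2 * (1 - rel_w))
        s = reliability_summary(rel_p, rel_w)
        assert lv.var_bias_analytical(Cp, Cw, 6) == pytest.approx(
            lv.var_bias_approx(s, sigma_g2, 6))


class TestVarDispersion:
    def test_hand_trace_algebra(self):
        n = 4
        G = 2 * np.eye(n)      # G - C22_p = I and C22_p - C22_w = I
        Cp = np.eye(n)
        Cw = np.zeros((n, n))
        t = centered_identity_trace(n)
        expected = t / (2 * t + t**2)   # 3 / 15 = 0.2
        assert lv.var_dispersion_analytical(G, Cp, Cw) == pytest.approx(expected)
        assert lv.var_dispersion_analytical(G, Cp, Cp) == 0.0

    def test_approx_modes(self):
        s = reliability_summary([0.5, 0.5], [1.0, 1.0])
        assert lv.var_dispersion_approx(s, 2, mode="per_animal") == pytest.approx(0.25)
        assert lv.var_dispersion_approx(
            reliability_summary([0.3, 0.4], [0.3, 0.4]), 2, mode="per_animal") == 0.0
        assert lv.var_dispersion_approx(
            reliability_summary([0.3, 0.4], [0.3, 0.4]), 2, mode="constant_c") == 0.0
        with pytest.raises(ValueError):
            lv.var_dispersion_approx(reliability_summary([0, 0], [0, 0]), 2,
                                     mode="constant_c")

    def test_modes_agree_for_homogeneous_reliabilities(self):
        for rp, c, n in [(0.4, 1.5, 7), (0.2, 2.0, 30), (0.7, 1.1, 4)]:
            s = reliability_summary([rp] * n, [min(c * rp, 1.0)] * n)
            assert lv.var_dispersion_approx(s, n, "per_animal") == pytest.approx(
                lv.var_dispersion_approx(s, n, "constant_c"), rel=1e-12)


class TestVarReliability:
    def test_hand_trace_algebra(self):
        n = 4
        G = np.eye(n) + 0.0
        Cp = np.zeros((n, n))   # G - Cp = I, Cp - Cw = 0
        Cw = np.zeros((n, n))
        assert lv.var_reliability_analytical(G, Cp, Cw, n, 1.0) == pytest.approx(
            2 * centered_identity_trace(n) / 16)   # 0.375
        same = np.full((n, n), 0.1) + np.eye(n)
        assert lv.var_reliability_analytical(same, same, same, n, 1.0) == 0.0

    def test_approx_arithmetic_and_scaling(self):
        s = reliability_summary([0.5] * 100, [0.5] * 100)  # c = 1
        assert lv.var_reliability_approx(s, 1.0, 1.0, 100) == pytest.approx(0.005)
        assert lv.var_reliability_approx(
            reliability_summary([0.0] * 5, [0.0] * 5), 1.0, 1.0, 5) == 0.0
        v1 = lv.var_reliability_approx(s, 1.0, 1.0, 100)
        v2 = lv.var_reliability_approx(s, 1.0, 2.0, 100)
        assert v1 / v2 == pytest.approx(4.0)


class TestWaldAndFisher:
    def test_wald_quantiles(self):
        r = lv.ci_wald(0.0, 1.0, SPEC)
        assert r.lower == pytest.approx(-1.959964, abs=1e-6)
        assert r.upper == pytest.approx(1.959964, abs=1e-6)
        r = lv.ci_wald(2.0, 0.0, SPEC)
        assert (r.lower, r.upper) == (2.0, 2.0)
        r = lv.ci_wald(0.0, 4.0, IntervalSpec(alpha=0.3173105078629141))
        assert r.upper == pytest.approx(2.0, rel=1e-6)  # est + 1 sd

    def test_fisher_frozen_values(self):
        r = lv.fisher_ci(0.5, 103, SPEC)
        assert r.lower == pytest.approx(0.3393075224832535, abs=1e-9)
        assert r.upper == pytest.approx(0.6323381504876256, abs=1e-9)
        # symmetric at zero, asymmetric elsewhere, always inside (-1, 1)
        r0 = lv.fisher_ci(0.0, 30, SPEC)
        assert r0.lower == pytest.approx(-r0.upper)
        assert 0.5 - r.lower != pytest.approx(r.upper - 0.5)
        assert -1 < r.lower < r.upper < 1
        with pytest.raises(ValueError):
            lv.fisher_ci(0.5, 3, SPEC)

    def test_fisher_width_shrinks_with_n(self):
        widths = [lv.fisher_ci(0.6, n, SPEC).upper - lv.fisher_ci(0.6, n, SPEC).lower
                  for n in (10, 50, 250, 1250)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_predictivity_reduces_to_fisher_at_h1(self):
        f = lv.fisher_ci(0.4, 50, SPEC)
        p = lv.predictivity_ci(0.4, 1.0, 50, SPEC)
        assert p.lower == pytest.approx(f.lower) and p.upper == pytest.approx(f.upper)

    def test_predictivity_frozen_values_and_range(self):
        r = lv.predictivity_ci(0.8, 0.5, 103, SPEC)
        assert r.lower == pytest.approx(0.6786150449665073, abs=1e-9)
        assert r.upper == pytest.approx(1.2646763009752513, abs=1e-9)
        r0 = lv.predictivity_ci(0.0, 0.5, 50, SPEC)
        assert r0.lower == pytest.approx(-r0.upper)
        with pytest.raises(ValueError):
            lv.predictivity_ci(1.2, 0.5, 50, SPEC)  # atanh undefined


class _Tuples:
    def __init__(self, p, w, y=None, sigma_gi2=1.0, h=1.0):
        self.uhat_p = np.asarray(p, float)
        self.uhat_w = np.asarray(w, float)
        self.ystar = None if y is None else np.asarray(y, float)
        self.sigma_gi2 = sigma_gi2
        self.h = h
        self.n = len(self.uhat_p)


class TestBootstrap:
    def test_constant_tuples_zero_width(self):
        inp = _Tuples([1.0] * 10, [2.0] * 10)
        r = lv.bootstrap_ci(inp, "bias", B=200, seed=0)
        assert r.lower == r.upper == pytest.approx(-1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        p = rng.standard_normal(30)
        inp = _Tuples(p, p + 0.3 * rng.standard_normal(30))
        a = lv.bootstrap_ci(inp, "dispersion", B=500, seed=42)
        b = lv.bootstrap_ci(inp, "dispersion", B=500, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        c = lv.bootstrap_ci(inp, "dispersion", B=500, seed=43)
        assert (a.lower, a.upper) != (c.lower, c.upper)

    def test_rejects_tiny_b(self):
        inp = _Tuples(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            lv.bootstrap_ci(inp, "bias", B=50)


class TestWilliams:
    def test_equal_correlations_give_null(self):
        r = lv.williams_test(0.4, 0.4, 0.5, 40)
        assert r.T == 0.0 and r.p_value == pytest.approx(1.0)
        assert r.df == 37

    def test_matches_independent_determinant_route(self):
        # oracle computes |R| as a 3x3 determinant and T from first principles
        rA, rB, rAB, n = 0.5, 0.3, 0.6, 100
        R = np.array([[1, rA, rB], [rA, 1, rAB], [rB, rAB, 1]])
        detR = np.linalg.det(R)
        rbar = (rA + rB) / 2
        T = (rA - rB) * math.sqrt(
            (n - 1) * (1 + rAB)
            / (2 * (n - 1) / (n - 3) * detR + rbar**2 * (1 - rAB) ** 3))
        res = lv.williams_test(rA, rB, rAB, n)
        assert res.detR == pytest.approx(detR, rel=1e-12)
        assert res.T == pytest.approx(T, rel=1e-12)
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(T), n - 3), rel=1e-12)

    def test_type_one_error_rate_under_null(self):
        # two predictors equally correlated with the shared variable
        rng = np.random.default_rng(7)
        n, reps = 50, 5000
        cov = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.6], [0.5, 0.6, 1.0]])
        L = np.linalg.cholesky(cov)
        rejections = 0
        X = rng.standard_normal((reps, n, 3)) @ L.T
        Xc = X - X.mean(axis=1, keepdims=True)
        ss = np.sqrt((Xc**2).sum(axis=1))
        ryA = (Xc[:, :, 0] * Xc[:, :, 1]).sum(axis=1) / (ss[:, 0] * ss[:, 1])
        ryB = (Xc[:, :, 0] * Xc[:, :, 2]).sum(axis=1) / (ss[:, 0] * ss[:, 2])
        rAB = (Xc[:, :, 1] * Xc[:, :, 2]).sum(axis=1) / (ss[:, 1] * ss[:, 2])
        for a, b, ab in zip(ryA, ryB, rAB):
            if lv.williams_test(a, b, ab, n).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_error_contracts(self):
        with pytest.raises(ValueError):
            lv.williams_test(0.5, 0.3, 1.0, 50)
        with pytest.raises(ValueError):
            lv.williams_test(0.5, 0.3, 0.5, 3)
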