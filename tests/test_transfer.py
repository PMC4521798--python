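"""Transfer functions and the Gaussian moment calculus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, dblquad

from ratechaos import transfer as tr


def gauss_quad(f, mu, s2, pts=None):
    """Adaptive-quadrature oracle for int f(mu + sqrt(s2) z) Dz."""
    w = lambda z: np.exp(-z * z / 2) / np.sqrt(2 * np.pi)
    return quad(lambda z: f(mu + np.sqrt(s2) * z) * w(z), -30, 30,
                points=pts, limit=400)[0]


ALL_TFS = [tr.sigmoid_erf(), tr.threshold_linear(), tr.threshold_power(2.0),
           tr.threshold_power(0.7), tr.lif(1.0)]


class TestPointwise:
    def test_examples(self):
        sg, L = tr.sigmoid_erf(), tr.lif(0.01)
        assert sg.g(0.0) == 0.5
        assert np.isclose(L.g(1.5), 1.0 / (0.01 * np.log(3.0)))
        assert tr.threshold_power(2.0).g(-3.0) == 0.0
        assert np.isclose(sg.g_prime(0.0), 1.0 / np.sqrt(2 * np.pi))
        assert tr.threshold_linear().g_prime(5.0) == 1.0
        assert tr.threshold_linear().g_prime(-5.0) == 0.0
        # antiderivative anchors
        assert np.isclose(sg.G(0.0), 1.0 / np.sqrt(2 * np.pi))
        assert tr.threshold_linear().G(2.0) == 2.0
        assert tr.threshold_power(2.0).G(3.0) == 9.0

    def test_sigmoid_symmetry(self, sigmoid):
        x = np.linspace(-4, 4, 41)
        assert np.allclose(sigmoid.g(-x), 1.0 - sigmoid.g(x))

    @pytest.mark.parametrize("tf", ALL_TFS, ids=lambda t: t.kind + str(t.gamma))
    def test_nonnegative_nondecreasing(self, tf):
        x = np.linspace(-5, 50, 3001)
        g = tf.g(x)
        assert np.all(g >= 0)
        assert np.all(np.diff(g) >= -1e-12)

    @given(st.floats(-20, 20))
    @settings(max_examples=50, deadline=None)
    def test_lif_zero_at_threshold_and_below(self, x):
        L = tr.lif(1.0)
        if x <= 1.0:
            assert L.g(x) == 0.0
        else:
            assert L.g(x) > 0.0

    @pytest.mark.parametrize("tf", ALL_TFS, ids=lambda t: t.kind + str(t.gamma))
    def test_G_is_antiderivative(self, tf):
        lo = tf.threshold if np.isfinite(tf.threshold) else -3.0
        xs = lo + np.array([0.31, 1.1, 2.7, 9.3])
        eps = 1e-5
        num = (tf.G(xs + eps) - tf.G(xs - eps)) / (2 * eps)
        assert np.allclose(num, tf.g(xs), rtol=2e-4, atol=1e-6)


class TestGaussMoments:
    def test_gauss_mean_basics(self, sigmoid, tlin):
        assert np.isclose(tr.gauss_mean(sigmoid.g, 0.0, 1.0), 0.5)
        assert np.isclose(tr.mean_rate(tlin, 0.0, 1.0),
                          1.0 / np.sqrt(2 * np.pi))
        assert np.isclose(tr.C_hat(tlin, 0.0, 1.0), 0.5)
        # sigma2 = 0 returns f(mu)
        assert tr.gauss_mean(sigmoid.g, 0.3, 0.0) == sigmoid.g(0.3)

    @pytest.mark.parametrize("mu,s", [(0.0, 1.0), (0.4, 2.3), (-1.1, 0.6)])
    @pytest.mark.parametrize(
        "tf", [tr.sigmoid_erf(), tr.threshold_linear(),
               tr.threshold_power(2.0), tr.threshold_power(0.7)],
        ids=lambda t: t.kind + str(t.gamma))
    def test_closed_forms_match_quadrature(self, tf, mu, s):
        pts = None
        if np.isfinite(tf.threshold):
            pts = [(tf.threshold - mu) / np.sqrt(s)]
        for name, closed, fn in [
            ("mean", tr.mean_rate(tf, mu, s), tf.g),
            ("second", tr.C_hat(tf, mu, s), lambda x: tf.g(x) ** 2),
            ("G", float(tr.smoothed_G(tf, np.float64(mu), s)), tf.G),
        ]:
            oracle = gauss_quad(fn, mu, s, pts)
            assert abs(closed - oracle) <= 1e-8 * max(1.0, abs(oracle)), name
        if tf.has_finite_gprime_sq and tf.gamma != 0.7:
            oracle = gauss_quad(lambda x: tf.g_prime(x) ** 2, mu, s, pts)
            assert abs(tr.C_hat_prime(tf, mu, s) - oracle) <= 1e-8

    def test_truncated_moments(self):
        F1, F2 = tr.truncated_moments(0.0, 1.0)
        assert np.isclose(F1, 1.0 / np.sqrt(2 * np.pi))
        assert np.isclose(F2, 0.5)
        F1, F2 = tr.truncated_moments(40.0, 2.0)
        assert np.isclose(F1, 40.0, rtol=1e-10)
        assert np.isclose(F2, 40.0**2 + 2.0, rtol=1e-10)
        F1, F2 = tr.truncated_moments(-40.0, 2.0)
        assert F1 < 1e-12 and F2 < 1e-12

    def test_divergent_moments_signalled(self):
        with pytest.raises(tr.DivergentMomentError):
            tr.C_hat_prime(tr.lif(1.0), 0.5, 1.0)
        with pytest.raises(tr.DivergentMomentError):
            tr.C_hat_prime(tr.threshold_power(0.4), 0.0, 1.0)

    def test_chat_prime_examples(self, tlin):
        assert tr.C_hat_prime(tlin, 0.0, 1.0) == 0.5
        assert tr.C_hat_prime(tlin, 50.0, 1.0) > 1.0 - 1e-12


class TestCTilde:
    def test_limits(self, tlin, sigmoid):
        for tf, mu, s0 in [(tlin, 0.2, 1.3), (sigmoid, -0.5, 2.0)]:
            r = tr.mean_rate(tf, mu, s0)
            assert np.isclose(tr.C_tilde(tf, mu, s0, 0.0), r * r, atol=1e-12)
            assert np.isclose(tr.C_tilde(tf, mu, s0, s0),
                              tr.C_hat(tf, mu, s0), atol=1e-10)

    def test_monotone_in_sigma(self, tlin):
        s0 = 1.7
        vals = [tr.C_tilde(tlin, 0.1, s0, s) for s in np.linspace(0, s0, 25)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_out_of_domain(self, tlin):
        with pytest.raises(ValueError):
            tr.C_tilde(tlin, 0.0, 1.0, 1.5)

    def test_nested_quadrature_oracle(self, tlin):
        # C~ for sigma in (0, sigma0): against a brute-force double integral
        mu, s0, s = 0.0, 1.0, 0.5
        v = s0 - s

        def inner(z):
            kink = -(mu + np.sqrt(s) * z) / np.sqrt(v)
            return quad(lambda xi: tlin.g(mu + np.sqrt(v) * xi
                                          + np.sqrt(s) * z)
                        * np.exp(-xi * xi / 2) / np.sqrt(2 * np.pi),
                        -14, 14, limit=300, epsabs=1e-13, epsrel=1e-12,
                        points=[np.clip(kink, -14, 14)])[0]

        oracle = quad(lambda z: inner(z) ** 2
                      * np.exp(-z * z / 2) / np.sqrt(2 * np.pi),
                      -14, 14, limit=300, epsabs=1e-13, epsrel=1e-12)[0]
        assert abs(tr.C_tilde(tlin, mu, s0, s) - oracle) < 1e-9

    def test_sigmoid_full_covariance_montecarlo(self, sigmoid, rng):
        # C~(sigma0) = E[g(x)^2] with x ~ N(0,1): Monte-Carlo cross-check
        x = rng.normal(size=2_000_000)
        mc = np.mean(sigmoid.g(x) ** 2)
        assert abs(tr.C_tilde(sigmoid, 0.0, 1.0, 1.0) - mc) < 2e-3
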