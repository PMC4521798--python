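"""One-population mean-field theory: fixed point, criticality, chaos."""

import numpy as np
import pytest

from ratechaos import transfer as tr
from ratechaos.dmft import onepop as d1


class TestFixedPoint:
    def test_balance_rate_kinf(self, sigmoid):
        fp = d1.solve_fixed_point(sigmoid, 4.0, 1.0)
        assert np.isclose(fp.rate, 0.25, atol=1e-12)
        # residuals of both self-consistency equations
        assert abs(fp.sigma - 16.0 * tr.C_hat(sigmoid, fp.mu, fp.sigma)) < 1e-10
        assert abs(tr.mean_rate(sigmoid, fp.mu, fp.sigma) - 0.25) < 1e-10

    def test_finite_k_lif_rate(self, lif_unit):
        # J0=2, I0=0.3, K=800: mean rate close to 15 Hz (tau_m = 10 ms)
        fp = d1.solve_fixed_point(lif_unit, 2.0, 0.3, K=800)
        assert abs(100.0 * fp.rate - 15.0) < 1.5

    def test_tl_critical_mu_is_zero(self, tlin):
        Jc = d1.critical_coupling(tlin, 1.0)
        fp = d1.solve_fixed_point(tlin, Jc, 1.0)
        assert abs(fp.mu) < 1e-6

    def test_q_property(self, sigmoid):
        fp = d1.solve_fixed_point(sigmoid, 6.0, 1.0)
        assert np.isclose(fp.q, fp.sigma / 36.0)


class TestCriticalCoupling:
    def test_sigmoid_value(self, sigmoid):
        assert abs(d1.critical_coupling(sigmoid, 1.0) - 4.995) < 5e-3

    @pytest.mark.parametrize("I0", [0.5, 1.0, 2.0])
    def test_threshold_linear_sqrt2_any_drive(self, tlin, I0):
        assert abs(d1.critical_coupling(tlin, I0) - np.sqrt(2)) < 1e-9

    def test_divergent_cases_signal(self, lif_unit):
        with pytest.raises(d1.AlwaysUnstableError):
            d1.critical_coupling(lif_unit, 0.3)
        with pytest.raises(d1.AlwaysUnstableError):
            d1.critical_coupling(tr.threshold_power(0.4), 1.0)

    def test_nonmonotone_in_gamma(self):
        # Jc rises from gamma=1 toward ~0.7 then collapses toward 1/2
        jc = {g: d1.critical_coupling(tr.threshold_power(g), 1.0, K=400)
              for g in (0.55, 0.7, 1.0)}
        assert jc[0.7] > jc[1.0] > jc[0.55]


class TestPotentialAndChaos:
    def test_potential_stationary_at_fixed_point(self, sigmoid):
        fp = d1.solve_fixed_point(sigmoid, 6.0, 1.0)
        pe = d1.potential(sigmoid, 6.0, fp.mu, fp.sigma, fp.sigma)
        assert abs(pe.Vp) < 1e-8

    def test_potential_derivative_finite_difference(self, sigmoid):
        fp = d1.solve_fixed_point(sigmoid, 15.0, 1.0)
        s0 = fp.sigma
        h = 1e-5 * s0
        for s in (0.3 * s0, 0.7 * s0):
            Vm = d1.potential(sigmoid, 15.0, fp.mu, s0, s - h).V
            Vp_ = d1.potential(sigmoid, 15.0, fp.mu, s0, s + h).V
            pe = d1.potential(sigmoid, 15.0, fp.mu, s0, s)
            assert abs((Vp_ - Vm) / (2 * h) - pe.Vp) < 1e-6 * max(1, abs(pe.Vp))

    def test_below_critical_raises(self, sigmoid):
        with pytest.raises(d1.NoChaoticSolution):
            d1.solve_chaotic(sigmoid, 4.0, 1.0)

    def test_chaotic_solution_sigmoid(self, sigmoid):
        sol = d1.solve_chaotic(sigmoid, 15.0, 1.0)
        assert sol.sigma0 > sol.sigma_inf > 0
        assert np.all(np.diff(sol.sigma_of_tau) <= 1e-10)  # monotone decay
        assert sol.energy_drift <= 1e-6
        # self-consistency of the plateau: sigma_inf = J0^2 C~(sigma_inf)
        resid = sol.sigma_inf - 15.0**2 * tr.C_tilde(
            sigmoid, sol.mu, sol.sigma0, sol.sigma_inf)
        assert abs(resid) < 1e-8 * sol.sigma0
        # rhs vanishes at the fixed point and is negative at sigma0
        fp = d1.solve_fixed_point(sigmoid, 15.0, 1.0)
        assert abs(d1.pac_ode_rhs(sigmoid, 15.0, fp.mu, fp.sigma,
                                  fp.sigma)) < 1e-9
        assert d1.pac_ode_rhs(sigmoid, 15.0, sol.mu, sol.sigma0,
                              sol.sigma0) < 0

    def test_supercritical_amplitude_shrinks(self, tlin):
        Jc = np.sqrt(2)
        a1 = d1.solve_chaotic(tlin, Jc * 1.02, 1.0).amplitude
        a2 = d1.solve_chaotic(tlin, Jc * 1.01, 1.0).amplitude
        assert 0 < a2 < a1
        # quadratic vanishing: halving delta shrinks amplitude ~4x
        assert 2.5 < a1 / a2 < 6.0


class TestRateDistribution:
    def test_normalization_thresholded(self, tlin):
        fp = d1.solve_fixed_point(tlin, 1.2, 1.0)
        dist = d1.rate_distribution_fixed_point(fp)
        from scipy.integrate import quad
        cont = quad(dist.pdf, 1e-12, 50.0, limit=300)[0]
        assert abs(dist.atom_mass + cont - 1.0) < 1e-8

    def test_atom_vanishes_far_above_threshold(self, lif_unit):
        fp = d1.DMFTFixedPoint(mu=30.0, sigma=1.0, rate=29.0, J0=1.0,
                               I0=1.0, K=np.inf, tf=lif_unit)
        dist = d1.rate_distribution_fixed_point(fp)
        assert dist.atom_mass < 1e-12

    def test_lif_distribution_matches_histogram(self, lif_unit):
        # change-of-variables density integrates to the sub/supra split
        fp = d1.solve_fixed_point(lif_unit, 2.0, 0.3, K=800)
        dist = d1.rate_distribution_fixed_point(fp)
        from scipy.integrate import quad
        cont = quad(dist.pdf, 1e-9, 25.0, limit=400,
                    points=[0.01, 0.1, 0.5, 1.0, 3.0])[0]
        assert abs(dist.atom_mass + cont - 1.0) < 1e-6
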