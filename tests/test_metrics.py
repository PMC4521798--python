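"""PAC estimation, cosh fits, Lyapunov procedure, stability fraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratechaos import transfer as tr
from ratechaos.metrics import (PACCurve, fit_pac, max_lyapunov, pac_estimate,
                               stability_fraction)


class TestPACEstimator:
    def test_constant_traces_give_flat_population_variance(self, rng):
        c = rng.normal(0, 2, size=400)
        traces = np.tile(c[:, None], (1, 300))
        pac = pac_estimate(traces, dt=0.1, max_lag=5.0)
        assert np.allclose(pac.values, c.var(), rtol=1e-10)

    def test_random_phase_sines(self, rng):
        # f_i = A sin(w t + phi_i), phi_i uniform: sigma(k) -> (A^2/2) cos(w k dt)
        N, T, dt, A, w = 3000, 4096, 0.25, 1.7, 0.9
        t = np.arange(T) * dt
        phi = rng.uniform(0, 2 * np.pi, N)
        traces = A * np.sin(w * t[None, :] + phi[:, None])
        pac = pac_estimate(traces, dt=dt, max_lag=20.0)
        expected = (A**2 / 2) * np.cos(w * pac.lags)
        assert np.max(np.abs(pac.values - expected)) < 0.02 * A**2

    def test_lag_bound(self, rng):
        with pytest.raises(ValueError):
            pac_estimate(rng.normal(size=(10, 50)), dt=1.0, max_lag=60.0)


class TestFitPAC:
    def test_self_fit_recovery(self):
        t = np.linspace(0, 30, 400)
        pac = PACCurve(t, 2.0 / np.cosh(t / 3.0) ** 2)
        fit = fit_pac(pac, family="cosh2")
        assert abs(fit.amplitude - 2.0) < 1e-6
        assert abs(fit.tau_dec - 3.0) < 1e-6

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        t = np.linspace(0, 40, 300)
        y = 1.3 / np.cosh(t / 4.0)
        f1 = fit_pac(PACCurve(t, y), "cosh1")
        f2 = fit_pac(PACCurve(t, c * y), "cosh1")
        assert np.isclose(f2.amplitude, c * f1.amplitude, rtol=1e-6)
        assert np.isclose(f2.tau_dec, f1.tau_dec, rtol=1e-6)

    def test_offset_family(self):
        t = np.linspace(0, 50, 500)
        y = 0.4 + 1.1 / np.cosh(t / 5.0)
        fit = fit_pac(PACCurve(t, y), "cosh1_offset")
        assert abs(fit.offset - 0.4) < 0.02
        assert abs(fit.amplitude - 1.1) < 0.05
        assert abs(fit.tau_dec - 5.0) < 0.3

    def test_non_decaying_raises(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(RuntimeError):
            fit_pac(PACCurve(t, np.ones_like(t)), "cosh1")


class TestLyapunov:
    def test_linear_flow_exact(self):
        # dh/dt = -h/tau integrated by Euler: Lambda = ln(1 - dt/tau)/dt
        tau = 2.0

        class Lin:
            def __init__(self, state):
                self.state = state
                self.dt = tau / 20.0

            def advance(self, T):
                n = int(round(T / self.dt))
                self.state *= (1.0 - self.dt / tau) ** n

            def copy(self):
                return Lin(self.state.copy())

        dyn = Lin(np.linspace(1, 2, 40))
        est = max_lyapunov(dyn, tau_ref=tau, n_resets=40, transient=0.0)
        expected = np.log(1 - dyn.dt / tau) / dyn.dt
        assert abs(est.Lambda - expected) < 1e-6

    def test_sign_change_across_transition(self, sigmoid):
        from ratechaos.network import (NetworkParams, OnePopRateDynamics,
                                       sample_connectivity)
        N, K = 2000, 200
        C = sample_connectivity(N, K, seed=11)
        out = {}
        for J0 in (4.0, 15.0):
            p = NetworkParams(N=N, K=K, J0=J0, I0=1.0, tau=1.0, tf=sigmoid,
                              seed=11)
            est = max_lyapunov(OnePopRateDynamics(p, C), tau_ref=1.0,
                               n_resets=40, transient=80.0)
            out[J0] = est.Lambda
        assert out[4.0] < 0 < out[15.0]

    def test_two_seeds_agree_in_chaotic_regime(self, sigmoid):
        from ratechaos.network import (NetworkParams, OnePopRateDynamics,
                                       sample_connectivity)
        N, K = 2000, 200
        C = sample_connectivity(N, K, seed=12)
        p = NetworkParams(N=N, K=K, J0=15.0, I0=1.0, tau=1.0, tf=sigmoid,
                          seed=12)
        vals = []
        for s in (0, 1):
            dyn = OnePopRateDynamics(p, C)
            dyn.state += 0.01 * np.random.default_rng(s).normal(size=N)
            est = max_lyapunov(dyn, tau_ref=1.0, n_resets=50, transient=80.0)
            vals.append(est.Lambda)
        assert abs(vals[0] - vals[1]) < 0.1 * abs(np.mean(vals))


class TestStabilityFraction:
    def test_transition_bracket(self, tlin):
        # threshold-linear: the 50% line sits near the critical coupling
        res = stability_fraction(
            tlin, J0_grid=[0.9, 1.2, 1.5, 1.9, 2.3], I0=1.0, N=1000, K=100,
            n_realizations=10, transient=80.0, duration=40.0, seed=3)
        assert res.fraction_unstable[0] <= 20.0
        assert res.fraction_unstable[-1] >= 80.0
        assert 0.9 < res.J_m < 2.1
        assert res.J_at(95.0) > res.J_at(5.0)

    def test_weak_coupling_all_stable(self, tlin):
        res = stability_fraction(tlin, J0_grid=[0.2], I0=1.0, N=500, K=50,
                                 n_realizations=6, transient=60.0,
                                 duration=30.0, seed=4)
        assert res.fraction_unstable[0] == 0.0
        assert np.isnan(res.J_m)
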