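"""Connectivity sampling and rate-model integration."""

import numpy as np
import pytest

from ratechaos import transfer as tr
from ratechaos.network import (NetworkParams, sample_connectivity,
                               simulate_rate_onepop, simulate_rate_twopop)


class TestConnectivity:
    def test_dense_limit(self):
        C = sample_connectivity(4, 4, seed=0)
        assert np.all(C.matrix.toarray() == 1)

    def test_empty(self):
        C = sample_connectivity(10, 0, seed=0)
        assert C.matrix.nnz == 0

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            sample_connectivity(10, 11)

    def test_mean_in_degree(self):
        C = sample_connectivity(1000, 100, seed=3)
        assert 85 <= C.mean_in_degree() <= 115

    def test_reproducible_and_blockwise_independent(self):
        a = sample_connectivity(200, 20, seed=7, two_pop=True)
        b = sample_connectivity(200, 20, seed=7, two_pop=True)
        for k in a.blocks:
            assert (a.blocks[k] != b.blocks[k]).nnz == 0
        assert (a.blocks["EE"] != a.blocks["II"]).nnz > 0


class TestOnePopRate:
    def test_uncoupled_exponential_relaxation(self, sigmoid):
        # J0 = 0: h_i -> sqrt(K) I0 with time constant tau, exactly solvable
        N, K = 50, 10
        p = NetworkParams(N=N, K=K, J0=0.0, I0=1.0, tau=1.0, tf=sigmoid,
                          seed=2)
        C = sample_connectivity(N, K, seed=2)
        h0 = np.full(N, 0.5)
        traj = simulate_rate_onepop(p, C, h0=h0, T=3.0, dt=0.05,
                                    record_stride=1, n_record=N)
        target = np.sqrt(K) * 1.0
        # Euler factor per step: (1 - dt/tau)
        expected = target + (0.5 - target) * (1 - 0.05) ** (traj.times / 0.05)
        assert np.allclose(traj.h[0], expected, rtol=1e-12)

    def test_determinism(self, sigmoid):
        p = NetworkParams(N=300, K=30, J0=6.0, I0=1.0, tau=1.0, tf=sigmoid,
                          seed=5)
        C = sample_connectivity(300, 30, seed=5)
        a = simulate_rate_onepop(p, C, T=20.0)
        b = simulate_rate_onepop(p, C, T=20.0)
        assert np.array_equal(a.h, b.h)

    def test_fixed_point_below_critical(self, sigmoid):
        # J0 = 4 < Jc ~ 5: inputs freeze
        N, K = 4000, 400
        p = NetworkParams(N=N, K=K, J0=4.0, I0=1.0, tau=1.0, tf=sigmoid,
                          seed=8)
        C = sample_connectivity(N, K, seed=8)
        traj = simulate_rate_onepop(p, C, T=150.0, record_start=100.0,
                                    record_stride=4, n_record=500)
        assert float(np.mean(np.var(traj.h, axis=1))) < 1e-9

    def test_chaotic_balance_above_critical(self, sigmoid):
        # J0 = 15: sustained fluctuations and mean rate ~ I0/J0
        N, K = 4000, 400
        p = NetworkParams(N=N, K=K, J0=15.0, I0=1.0, tau=1.0, tf=sigmoid,
                          seed=9)
        C = sample_connectivity(N, K, seed=9)
        traj = simulate_rate_onepop(p, C, T=120.0, record_start=40.0,
                                    record_stride=4, n_record=1000)
        assert float(np.mean(np.var(traj.h, axis=1))) > 1e-3
        rate = float(np.mean(sigmoid.g(traj.h)))
        # finite-K balance: r = I0/J0 - mu/(sqrt(K) J0) with mu the mean input
        mu = float(np.mean(traj.h))
        predicted = 1.0 / 15.0 - mu / (np.sqrt(K) * 15.0)
        assert abs(rate - predicted) < 0.1 * predicted
        assert abs(rate - 1.0 / 15.0) < 0.5 / 15.0


class TestTwoPopRate:
    def test_all_zero_couplings(self, tlin):
        p = NetworkParams(N=100, K=10, J0=np.zeros((2, 2)), I0=(0.5, 0.25),
                          tau=1.0, tf=tlin, seed=1)
        C = sample_connectivity(100, 10, seed=1, two_pop=True)
        traj = simulate_rate_twopop(p, C, T=30.0, record_stride=5,
                                    n_record=50)
        sK = np.sqrt(10)
        assert np.allclose(traj.h["E"][:, -1], 0.5 * sK, atol=1e-6)
        assert np.allclose(traj.h["I"][:, -1], 0.25 * sK, atol=1e-6)

    def test_balance_rates(self, tlin):
        # II-driven chaotic regime: rates near the balance solution
        J0 = np.array([[0.0, 0.8], [10.0, 6.0]])
        p = NetworkParams(N=2000, K=200, J0=J0, I0=(1.0, 1.0), tau=1.0,
                          tf=tlin, seed=4)
        C = sample_connectivity(2000, 200, seed=4, two_pop=True)
        traj = simulate_rate_twopop(p, C, T=120.0, record_start=60.0,
                                    record_stride=10, n_record=500)
        rE = float(np.mean(tlin.g(traj.h["E"])))
        rI = float(np.mean(tlin.g(traj.h["I"])))
        # finite-K balance: I0^a + J^aE rE - J^aI rI = mu^a / sqrt(K)
        muE = float(np.mean(traj.h["E"]))
        muI = float(np.mean(traj.h["I"]))
        sK = np.sqrt(200)
        assert abs(1.0 + 0.0 * rE - 0.8 * rI - muE / sK) < 0.05
        assert abs(1.0 + 10.0 * rE - 6.0 * rI - muI / sK) < 0.3
        # and the K->inf balance holds to O(1/sqrt(K))
        assert abs(rI - 1.25) < 8.0 / sK
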