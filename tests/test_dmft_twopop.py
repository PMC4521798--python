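"""Two-population mean-field theory: balance, onset, reductions."""

import numpy as np
import pytest

from ratechaos import transfer as tr
from ratechaos.dmft import onepop as d1, twopop as d2


def J(jee, jei, jie, jii):
    return np.array([[jee, jei], [jie, jii]], dtype=float)


class TestFixedPoint:
    def test_e_silencing_exact(self, tlin):
        # K->inf: r^E hits zero at J0^II = I0^I J0^EI / I0^E
        b = d2.e_silencing_boundary(tlin, J(0, 0.8, 3, 1), (1.0, 1.0))
        assert abs(b - 0.8) < 1e-12

    def test_silent_branch_below_boundary(self, tlin):
        mf = d2.solve_twopop_fixed_point(tlin, J(0, 0.8, 3, 0.5), (1.0, 1.0))
        assert not mf.balanced
        assert mf.r_E == 0.0
        assert np.isclose(mf.r_I, 1.0 / 0.5)

    def test_comparable_rates_at_large_jii(self, tlin):
        mf = d2.solve_twopop_fixed_point(tlin, J(0, 0.8, 3, 6), (1.0, 1.0))
        assert mf.balanced
        assert 0.2 < mf.r_I / mf.r_E < 5.0

    def test_decoupled_reduces_to_onepop(self, tlin):
        mf = d2.solve_twopop_fixed_point(tlin, J(0, 0, 0, 1.2), (0.0, 1.0))
        fp = d1.solve_fixed_point(tlin, 1.2, 1.0)
        assert np.isclose(mf.mu_I, fp.mu, atol=1e-10)
        assert np.isclose(mf.sigma_I, fp.sigma, atol=1e-10)

    def test_finite_k_residuals(self, tlin):
        K = 400
        mf = d2.solve_twopop_fixed_point(tlin, J(0, 0.8, 10, 6), (1, 1), K=K)
        sK = np.sqrt(K)
        # balance holds to O(mu/sqrt(K)) exactly
        assert abs(1 - 0.8 * mf.r_I - mf.mu_E / sK) < 1e-9
        assert abs(1 + 10 * mf.r_E - 6 * mf.r_I - mf.mu_I / sK) < 1e-9
        # variance equations
        CE = tr.C_hat(tlin, mf.mu_E, mf.sigma_E)
        CI = tr.C_hat(tlin, mf.mu_I, mf.sigma_I)
        assert abs(mf.sigma_E - 0.8**2 * CI) < 1e-9
        assert abs(mf.sigma_I - (100 * CE + 36 * CI)) < 1e-9


class TestOnset:
    def test_pure_ii_equals_onepop_jc(self, tlin):
        out = d2.chaos_onset_surface(tlin, J(0, 0, 0, 0), (0.0, 1.0),
                                     "II", (1.0, 3.0))
        assert len(out) == 1
        assert abs(out[0]["value"] - np.sqrt(2)) < 1e-9

    def test_label_swap_symmetry(self, tlin):
        # the onset combination is invariant under exchanging the roles of
        # the populations together with their couplings
        mf = d2.solve_twopop_fixed_point(tlin, J(0, 0.8, 10, 6), (1, 1),
                                         K=400)
        swapped = d2.TwoPopMeanField(
            mu_E=mf.mu_I, mu_I=mf.mu_E, sigma_E=mf.sigma_I,
            sigma_I=mf.sigma_E, r_E=mf.r_I, r_I=mf.r_E,
            J0=np.array([[mf.J0[1, 1], mf.J0[1, 0]],
                         [mf.J0[0, 1], mf.J0[0, 0]]]),
            I0=mf.I0[::-1], K=mf.K, tf=mf.tf)
        assert np.isclose(d2.onset_criterion(mf),
                          d2.onset_criterion(swapped), atol=1e-12)

    def test_eie_loop_reduction(self, tlin):
        # J0^EE = J0^II = 0: criterion reduces to (JEI JIE)^2 C'_E C'_I = 1
        mf = d2.solve_twopop_fixed_point(tlin, J(0, 0.8, 10, 2), (1, 1),
                                         K=400)
        mf0 = d2.TwoPopMeanField(mf.mu_E, mf.mu_I, mf.sigma_E, mf.sigma_I,
                                 mf.r_E, mf.r_I, J(0, 0.8, 10, 0), mf.I0,
                                 mf.K, mf.tf)
        CpE = tr.C_hat_prime(tlin, mf.mu_E, mf.sigma_E)
        CpI = tr.C_hat_prime(tlin, mf.mu_I, mf.sigma_I)
        assert np.isclose(d2.onset_criterion(mf0),
                          (0.8 * 10) ** 2 * CpE * CpI - 1.0, atol=1e-12)

    def test_onset_moves_with_k(self, tlin):
        # finite-K re-entrance: K=400 onset differs from K->inf onset
        o400 = d2.chaos_onset_surface(tlin, J(0, 0.8, 0, 1.0), (1, 1),
                                      "IE", (0.2, 30.0), K=400)
        oinf = d2.chaos_onset_surface(tlin, J(0, 0.8, 0, 1.0), (1, 1),
                                      "IE", (0.2, 30.0), K=np.inf)
        assert len(o400) == 1 and len(oinf) == 1
        assert o400[0]["value"] < oinf[0]["value"]


class TestSlowPathway:
    def test_stationarity_and_onset_agreement(self, tlin):
        I0 = (1.0, 1.0)
        J0 = J(0, 0.8, 10, 2)
        mf = d2.solve_twopop_fixed_point(tlin, J0, I0, K=400)
        sIE = mf.sigma_block("I", "E")
        Vp, Vpp = d2.slow_pathway_potential(tlin, J0, I0, sIE, mf=mf, K=400)
        assert abs(Vp) < 1e-8
        # V'' = 0 at the fixed point iff the general onset criterion is 0:
        # locate the onset along J0^IE and check V'' vanishes there
        out = d2.chaos_onset_surface(tlin, J(0, 0.8, 0, 1.0), (1, 1),
                                     "IE", (0.2, 30.0), K=400)
        Jstar = out[0]["value"]
        mfs = out[0]["state"]
        _, Vpp_star = d2.slow_pathway_potential(
            tlin, J(0, 0.8, Jstar, 1.0), I0,
            mfs.sigma_block("I", "E"), mf=mfs, K=400)
        assert abs(Vpp_star) < 1e-6

    def test_no_feedback_no_instability(self, tlin):
        # J0^EI = 0: V'' = -1 (the EIE product term vanishes)
        I0 = (1.0, 0.5)
        J0 = J(0, 0, 4, 1.0)
        mf = d2.solve_twopop_fixed_point(tlin, J0, I0, K=400)
        sIE = mf.sigma_block("I", "E")
        _, Vpp = d2.slow_pathway_potential(tlin, J0, I0, sIE, mf=mf, K=400)
        assert np.isclose(Vpp, -1.0, atol=1e-10)


class TestPACSystem:
    def test_zero_couplings_zero_solution(self, tlin):
        mf = d2.TwoPopMeanField(0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                                J(0, 0, 0, 0), (0.0, 0.0), np.inf, tlin)
        rhs = d2.twopop_pac_rhs(tlin, mf, np.zeros((2, 2)), np.zeros((2, 2)),
                                np.ones((2, 2)))
        assert np.allclose(rhs, 0.0)

    def test_rhs_vanishes_at_fixed_point(self, tlin):
        mf = d2.solve_twopop_fixed_point(tlin, J(0, 0.8, 10, 6), (1, 1),
                                         K=400)
        sig = np.array([[mf.sigma_block("E", "E"), mf.sigma_block("E", "I")],
                        [mf.sigma_block("I", "E"), mf.sigma_block("I", "I")]])
        rhs = d2.twopop_pac_rhs(tlin, mf, sig, sig, np.ones((2, 2)))
        assert np.max(np.abs(rhs)) < 1e-7
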