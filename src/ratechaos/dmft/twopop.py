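"""Mean-field theory of the two-population (excitatory-inhibitory) network.

Each population's net input h^a = h^{aE} - h^{aI} + sqrt(K) I0^a is Gaussian
with mean mu^a and variance sigma^a = sigma^{aE} + sigma^{aI}.  At a fixed
point the self-consistency reads (a, b in {E, I})

    mu^a    = sqrt(K) (I0^a + J0^{aE} r^E - J0^{aI} r^I)   (balance as K->inf)
    r^b     = int Dz g(mu^b + sqrt(sigma^b) z)
    sigma^a = (J0^{aE})^2 Chat(mu^E, sigma^E) + (J0^{aI})^2 Chat(mu^I, sigma^I)

and the fixed point loses stability to chaos when

    1 = (J0^EE)^2 C'_E + (J0^II)^2 C'_I
        + [(J0^EI J0^IE)^2 - (J0^EE J0^II)^2] C'_E C'_I

with C'_a = Chat'(mu^a, sigma^a) the Gaussian second moment of g'.  In the
K -> infinity balanced limit the rates are fixed linearly by the external
drives; the excitatory population falls silent (r^E = 0, unbalanced regime)
when J0^II < I0^I J0^EI / I0^E — the E-silencing boundary.

When one synapse type is much slower than the rest the PAC dynamics reduce
to motion in a one-dimensional potential over that pathway's covariance
(``slow_pathway_potential``); the general four-PAC second-order system is
exposed as ``twopop_pac_rhs`` for numerical exploration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .. import transfer as tr
from ..transfer import TransferFunction

__all__ = [
    "TwoPopMeanField",
    "solve_twopop_fixed_point",
    "onset_criterion",
    "chaos_onset_surface",
    "e_silencing_boundary",
    "slow_pathway_potential",
    "twopop_pac_rhs",
]

_IDX = {"E": 0, "I": 1}


@dataclass
class TwoPopMeanField:
    """Fixed-point mean-field state of the two-population network."""

    mu_E: float
    mu_I: float
    sigma_E: float        # net-input variance sigma^E = sigma^{EE}+sigma^{EI}
    sigma_I: float
    r_E: float
    r_I: float
    J0: np.ndarray        # 2x2, [post, pre], order (E, I)
    I0: tuple
    K: float
    tf: TransferFunction
    balanced: bool = True  # False on the r_E = 0 (unbalanced) branch

    def sigma_block(self, post: str, pre: str) -> float:
        """Per-pathway variance sigma^{ab} = (J0^{ab})^2 Chat(mu^b, sigma^b)."""
        mu = (self.mu_E, self.mu_I)[_IDX[pre]]
        s = (self.sigma_E, self.sigma_I)[_IDX[pre]]
        return self.J0[_IDX[post], _IDX[pre]] ** 2 * tr.C_hat(self.tf, mu, s)


def _balanced_rates(J0, I0):
    """Rates from the K->inf balance conditions (2x2 linear system):
    I0^a + J0^{aE} r^E - J0^{aI} r^I = 0."""
    A = np.array([[J0[0, 0], -J0[0, 1]], [J0[1, 0], -J0[1, 1]]])
    b = -np.asarray(I0, dtype=float)
    det = np.linalg.det(A)
    if abs(det) < 1e-14:
        raise RuntimeError("balance conditions are degenerate for these J0")
    return np.linalg.solve(A, b)


def solve_twopop_fixed_point(tf: TransferFunction, J0, I0, K: float = np.inf,
                             ) -> TwoPopMeanField:
    """Solve the four-equation fixed-point self-consistency.

    For K = inf the balanced branch pins (r^E, r^I) linearly; if that gives
    r^E < 0 the unbalanced branch (r^E = 0 exactly, E population silent) is
    returned instead.  Finite K solves the full system in
    (mu^E, mu^I, sigma^E, sigma^I).
    """
    J0 = np.asarray(J0, dtype=float)
    if np.any(J0 < 0):
        raise ValueError("couplings are magnitudes: J0 >= 0")

    if np.isinf(K):
        if J0[0].sum() == 0.0 and I0[0] == 0.0 and J0[1, 1] > 0:
            # E population fully decoupled and undriven: silent; the I
            # population reduces to the one-population problem
            rI = I0[1] / J0[1, 1]
            mu_I, s_I = _i_pop_state(tf, rI, J0[1, 1])
            return TwoPopMeanField(0.0, mu_I, 0.0, s_I, float(tf.g(0.0)), rI,
                                   J0, tuple(I0), K, tf)
        rE, rI = _balanced_rates(J0, I0)
        if rE < 0 or rI < 0:
            # unbalanced: the E population is silent; I balances alone
            if J0[1, 1] == 0:
                raise RuntimeError("no balanced or E-silent solution")
            rI = I0[1] / J0[1, 1]
            mu_I, s_I = _i_pop_state(tf, rI, J0[1, 1])
            # mu_E -> -inf at K=inf; E contributes nothing to any variance
            s_E = J0[0, 1] ** 2 * tr.C_hat(tf, mu_I, s_I)
            return TwoPopMeanField(-np.inf, mu_I, s_E, s_I, 0.0, rI,
                                   J0, tuple(I0), K, tf, balanced=False)

        def resid(x):
            muE, muI, sE, sI = x
            sE, sI = abs(sE), abs(sI)
            CE, CI = tr.C_hat(tf, muE, sE), tr.C_hat(tf, muI, sI)
            return [
                tr.mean_rate(tf, muE, sE) - rE,
                tr.mean_rate(tf, muI, sI) - rI,
                sE - (J0[0, 0] ** 2 * CE + J0[0, 1] ** 2 * CI),
                sI - (J0[1, 0] ** 2 * CE + J0[1, 1] ** 2 * CI),
            ]

        x0 = _initial_guess(tf, J0, (rE, rI))
        sol = root(resid, x0, method="hybr", tol=1e-13)
        if not sol.success or np.max(np.abs(resid(sol.x))) > 1e-9:
            raise RuntimeError(f"fixed-point solve failed: {sol.message}")
        muE, muI, sE, sI = sol.x
        return TwoPopMeanField(muE, muI, abs(sE), abs(sI), rE, rI,
                               J0, tuple(I0), K, tf)

    sK = np.sqrt(K)

    def resid(x):
        muE, muI, sE, sI = x
        sE, sI = abs(sE), abs(sI)
        rE = tr.mean_rate(tf, muE, sE)
        rI = tr.mean_rate(tf, muI, sI)
        CE, CI = tr.C_hat(tf, muE, sE), tr.C_hat(tf, muI, sI)
        return [
            muE - sK * (I0[0] + J0[0, 0] * rE - J0[0, 1] * rI),
            muI - sK * (I0[1] + J0[1, 0] * rE - J0[1, 1] * rI),
            sE - (J0[0, 0] ** 2 * CE + J0[0, 1] ** 2 * CI),
            sI - (J0[1, 0] ** 2 * CE + J0[1, 1] ** 2 * CI),
        ]

    try:
        rguess = np.clip(_balanced_rates(J0, I0), 1e-3, None)
    except RuntimeError:
        rguess = np.array([0.1, 0.1])
    x0 = _initial_guess(tf, J0, rguess)
    sol = root(resid, x0, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(resid(sol.x))) > 1e-9:
        # damped Picard sweep to land in Newton's basin, then retry
        x = x0.copy()
        for _ in range(400):
            muE, muI, sE, sI = x
            sE, sI = abs(sE), abs(sI)
            rE = tr.mean_rate(tf, muE, sE)
            rI = tr.mean_rate(tf, muI, sI)
            CE, CI = tr.C_hat(tf, muE, sE), tr.C_hat(tf, muI, sI)
            new = np.array([
                sK * (I0[0] + J0[0, 0] * rE - J0[0, 1] * rI),
                sK * (I0[1] + J0[1, 0] * rE - J0[1, 1] * rI),
                J0[0, 0] ** 2 * CE + J0[0, 1] ** 2 * CI,
                J0[1, 0] ** 2 * CE + J0[1, 1] ** 2 * CI,
            ])
            x = 0.9 * x + 0.1 * new
        sol = root(resid, x, method="hybr", tol=1e-13)
    if not sol.success or np.max(np.abs(resid(sol.x))) > 1e-9:
        raise RuntimeError(f"fixed-point solve failed: {sol.message}")
    muE, muI, sE, sI = sol.x
    sE, sI = abs(sE), abs(sI)
    return TwoPopMeanField(muE, muI, sE, sI,
                           tr.mean_rate(tf, muE, sE),
                           tr.mean_rate(tf, muI, sI),
                           J0, tuple(I0), K, tf)


def _i_pop_state(tf, rate, JII):
    """(mu, sigma) of the I population alone at pinned mean rate."""

    def mu_at(sigma):
        return _mu_at_rate(tf, rate, sigma)

    def resid(sigma):
        return sigma - JII ** 2 * tr.C_hat(tf, mu_at(sigma), sigma)

    grid = max(JII, 1.0) ** 2 * np.logspace(-12, 3, 140)
    prev = None
    for s in grid:
        val = resid(s)
        if prev is not None and prev[1] < 0 <= val:
            sig = brentq(resid, prev[0], s, xtol=1e-15, rtol=8.9e-16)
            return mu_at(sig), sig
        prev = (s, val)
    raise RuntimeError("no self-consistent I-population variance")


def _mu_at_rate(tf, rate, sigma):
    f = lambda mu: tr.mean_rate(tf, mu, sigma) - rate
    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16)


def _initial_guess(tf, J0, rates):
    rE, rI = max(rates[0], 1e-3), max(rates[1], 1e-3)
    sE = J0[0, 0] ** 2 * rE ** 2 + J0[0, 1] ** 2 * rI ** 2 + 0.5
    sI = J0[1, 0] ** 2 * rE ** 2 + J0[1, 1] ** 2 * rI ** 2 + 0.5
    muE = _mu_at_rate(tf, rE, sE)
    muI = _mu_at_rate(tf, rI, sI)
    return np.array([muE, muI, sE, sI])


# ---------------------------------------------------------------------------
# chaos onset
# ---------------------------------------------------------------------------


def onset_criterion(mf: TwoPopMeanField) -> float:
    """S - 1 where S is the two-population instability combination; the
    fixed point is unstable (chaos) when the return value is positive."""
    J0 = mf.J0
    CpE = (tr.C_hat_prime(mf.tf, mf.mu_E, mf.sigma_E)
           if np.isfinite(mf.mu_E) else 0.0)
    CpI = tr.C_hat_prime(mf.tf, mf.mu_I, mf.sigma_I)
    S = (J0[0, 0] ** 2 * CpE + J0[1, 1] ** 2 * CpI
         + ((J0[0, 1] * J0[1, 0]) ** 2 - (J0[0, 0] * J0[1, 1]) ** 2)
         * CpE * CpI)
    return S - 1.0


def chaos_onset_surface(tf: TransferFunction, J0_base, I0, scan: str,
                        scan_range, K: float = np.inf, n_grid: int = 60):
    """Root(s) of the onset criterion along one coupling axis.

    Parameters
    ----------
    scan : one of "EE", "EI", "IE", "II" — the coupling varied.
    scan_range : (lo, hi) interval searched.

    Returns a list of dicts (one per detected crossing) with the onset
    coupling and the mean-field state there; points where the solver leaves
    the balanced region are skipped.
    """
    J0_base = np.asarray(J0_base, dtype=float)
    i, j = _IDX[scan[0]], _IDX[scan[1]]

    def crit(val):
        J0 = J0_base.copy()
        J0[i, j] = val
        mf = solve_twopop_fixed_point(tf, J0, I0, K)
        if not mf.balanced:
            return None
        return onset_criterion(mf)

    grid = np.linspace(scan_range[0], scan_range[1], n_grid)
    vals = []
    for v in grid:
        try:
            vals.append(crit(v))
        except RuntimeError:
            vals.append(None)
    out = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa is None or fb is None or fa * fb > 0:
            continue
        x = brentq(lambda v: crit(v), a, b, xtol=1e-12, rtol=8.9e-16)
        J0 = J0_base.copy()
        J0[i, j] = x
        out.append({"scan": scan, "value": x,
                    "state": solve_twopop_fixed_point(tf, J0, I0, K)})
    return out


def e_silencing_boundary(tf: TransferFunction, J0_base, I0,
                         bracket=(1e-3, 50.0)) -> float:
    """J0^II below which the balanced r^E solution vanishes at K = infinity.

    Found as the root of r^E(J0^II) = 0 from the balance conditions; for
    J0^EE = 0 this reduces to J0^II = I0^I J0^EI / I0^E.
    """
    J0_base = np.asarray(J0_base, dtype=float)

    def rE(JII):
        J0 = J0_base.copy()
        J0[1, 1] = JII
        return _balanced_rates(J0, I0)[0]

    return brentq(rE, *bracket, xtol=1e-14, rtol=8.9e-16)


# ---------------------------------------------------------------------------
# PAC dynamics
# ---------------------------------------------------------------------------


def twopop_pac_rhs(tf: TransferFunction, mf: TwoPopMeanField, sigma_blocks,
                   sigma0_blocks, tau) -> np.ndarray:
    """Second derivatives of the four pathway PACs sigma^{ab}(tau_lag):

        (tau^{ab})^2 d2 sigma^{ab} = sigma^{ab} - (J0^{ab})^2 C~_b(sigma^b)

    where sigma^b = sigma^{bE} + sigma^{bI} sums the pathway covariances of
    the presynaptic population's net input.  Inputs/outputs are 2x2 arrays
    indexed [post, pre]; no closed potential exists in general, so this
    right-hand side backs relaxation/shooting explorations only.
    """
    sig = np.asarray(sigma_blocks, dtype=float)
    sig0 = np.asarray(sigma0_blocks, dtype=float)
    tau = np.broadcast_to(np.asarray(tau, dtype=float), (2, 2))
    mu = (mf.mu_E, mf.mu_I)
    s_net = sig[:, 0] + sig[:, 1]        # sigma^E, sigma^I at this lag
    s0_net = sig0[:, 0] + sig0[:, 1]
    out = np.empty((2, 2))
    for a in range(2):
        for b in range(2):
            if mf.J0[a, b] == 0.0:
                out[a, b] = sig[a, b] / tau[a, b] ** 2
                continue
            ct = tr.C_tilde(tf, mu[b], s0_net[b],
                            float(np.clip(s_net[b], -s0_net[b], s0_net[b])))
            out[a, b] = (sig[a, b] - mf.J0[a, b] ** 2 * ct) / tau[a, b] ** 2
    return out


def slow_pathway_potential(tf: TransferFunction, J0, I0, sigma_IE,
                           mf: TwoPopMeanField | None = None,
                           K: float = np.inf):
    """dV/dsigma^{IE} and V'' in the separation-of-time-scales limit where
    E-to-I synapses are much slower than the rest.

    The three fast pathways are slaved, sigma^{ab} = (J0^{ab})^2 C~_b, and

        dV/dsigma^IE = -sigma^IE + (J0^IE)^2 C~_E(sigma^E(sigma^IE)).

    Returns (Vp, Vpp) at the given sigma^IE.  At the fixed-point pathway
    variance the first derivative vanishes; V'' = 0 there reproduces the
    general onset condition — onset does not depend on the time constants.
    """
    J0 = np.asarray(J0, dtype=float)
    if mf is None:
        mf = solve_twopop_fixed_point(tf, J0, I0, K)
    mu = (mf.mu_E, mf.mu_I)
    s0 = (mf.sigma_E, mf.sigma_I)

    # slave the fast pathways at given sigma^IE: sigma^I is the scalar fixed
    # point of sigma^I = sigma^IE + (J0^II)^2 C~_I(sigma^I); then sigma^E
    def slave_I(sI):
        return sI - (sigma_IE + J0[1, 1] ** 2
                     * tr.C_tilde(tf, mu[1], s0[1],
                                  float(np.clip(sI, -s0[1], s0[1]))))

    sI = brentq(slave_I, -s0[1], s0[1], xtol=1e-13, rtol=8.9e-16)

    def slave_E(sE):
        return sE - (J0[0, 0] ** 2
                     * tr.C_tilde(tf, mu[0], s0[0],
                                  float(np.clip(sE, -s0[0], s0[0])))
                     + J0[0, 1] ** 2 * tr.C_tilde(tf, mu[1], s0[1], sI))

    sE = brentq(slave_E, -s0[0], s0[0], xtol=1e-13, rtol=8.9e-16)

    Vp = -sigma_IE + J0[1, 0] ** 2 * tr.C_tilde(tf, mu[0], s0[0], sE)

    # V'' from the chain rule through the slaved pathways
    dE = tr.C_tilde_prime(tf, mu[0], s0[0], sE)
    dI = tr.C_tilde_prime(tf, mu[1], s0[1], sI)
    denom = (1.0 - J0[0, 0] ** 2 * dE) * (1.0 - J0[1, 1] ** 2 * dI)
    Vpp = -1.0 + J0[1, 0] ** 2 * dE * J0[0, 1] ** 2 * dI / denom
    return Vp, Vpp
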