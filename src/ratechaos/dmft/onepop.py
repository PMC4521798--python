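"""Mean-field theory of one population of inhibitory rate neurons.

The network ``tau dh_i/dt = -h_i + sqrt(K) I0 - (J0/sqrt(K)) sum_j C_ij g(h_j)``
is described, for 1 << K << N, by a self-consistent Gaussian process for the
net input h: quenched (across-neuron) variance plus temporal fluctuations with
population-averaged autocovariance (PAC) sigma(tau).

Two stable regimes exist.  Below a critical coupling J_c the inputs freeze at
a fixed point: a Gaussian with mean mu and variance sigma = J0^2 q,

    mu    = sqrt(K) (I0 - J0 * r(mu, sigma)),
    sigma = J0^2 * int Dz g(mu + sqrt(sigma) z)^2,

(the first line becomes the balance condition r = I0/J0 for K -> infinity).
Above J_c the network is chaotic and sigma(tau) obeys Newtonian dynamics in
an effective potential,

    tau^2 sigma'' = sigma - J0^2 C~(sigma) = -dV/dsigma,

whose admissible solution decays monotonically from sigma0 = sigma(0) to
sigma_inf, a local maximum of V at the same potential height as sigma0
(energy conservation).  This module solves the fixed point, locates J_c,
constructs the chaotic solution and its PAC curve, and extracts the critical
scaling of the PAC amplitude and decorrelation time at chaos onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .. import transfer as tr
from ..transfer import TransferFunction, DivergentMomentError

__all__ = [
    "DMFTFixedPoint",
    "DMFTChaoticSolution",
    "PotentialEvaluation",
    "NoChaoticSolution",
    "AlwaysUnstableError",
    "solve_fixed_point",
    "critical_coupling",
    "potential",
    "pac_ode_rhs",
    "solve_chaotic",
    "rate_distribution_fixed_point",
    "critical_asymptotics",
]


class NoChaoticSolution(RuntimeError):
    """Raised when no admissible chaotic PAC exists (J0 <= Jc)."""


class AlwaysUnstableError(DivergentMomentError):
    """The g'^2 moment diverges: mean-field predicts chaos for any J0 > 0."""


@dataclass
class DMFTFixedPoint:
    """Self-consistent fixed-point state of the one-population theory."""

    mu: float
    sigma: float          # static input variance J0^2 q
    rate: float           # population mean rate [<g(h)>]
    J0: float
    I0: float
    K: float              # in-degree (np.inf for the strict balance limit)
    tf: TransferFunction

    @property
    def q(self) -> float:
        return self.sigma / self.J0**2


@dataclass
class DMFTChaoticSolution:
    """Chaotic-state solution: (mu, sigma0, sigma_inf) and the PAC curve."""

    mu: float
    sigma0: float
    sigma_inf: float
    tau_grid: np.ndarray
    sigma_of_tau: np.ndarray
    J0: float
    I0: float
    K: float
    tf: TransferFunction
    tau_syn: float = 1.0
    energy_drift: float = field(default=np.nan)

    @property
    def amplitude(self) -> float:
        return self.sigma0 - self.sigma_inf


@dataclass
class PotentialEvaluation:
    sigma: float
    sigma0: float
    mu: float
    V: float
    Vp: float


# ---------------------------------------------------------------------------
# fixed point
# ---------------------------------------------------------------------------


def _expand_brentq(f, lo, hi, grow=2.0, max_iter=200):
    flo, fhi = f(lo), f(hi)
    it = 0
    while flo * fhi > 0:
        it += 1
        if it > max_iter:
            raise RuntimeError(
                f"could not bracket root: f({lo})={flo}, f({hi})={fhi}")
        lo, hi = hi, hi + grow * (hi - lo)
        flo, fhi = fhi, f(hi)
    return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)


def _mu_of_variance(tf, J0, I0, K, sigma0):
    """Mean input solving the (finite-K or balance) rate equation at given
    instantaneous input variance sigma0."""
    if np.isinf(K):
        target = I0 / J0
        gmax = 1.0 if tf.kind == "sigmoid_erf" else np.inf
        if target >= gmax:
            raise RuntimeError(
                f"required balance rate {target} exceeds the range of g")
        f = lambda mu: tr.mean_rate(tf, mu, sigma0) - target
    else:
        sK = np.sqrt(K)
        f = lambda mu: mu - sK * (I0 - J0 * tr.mean_rate(tf, mu, sigma0))
    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2.0
        if lo < -1e9:
            raise RuntimeError("mu bracket failed (low side)")
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("mu bracket failed (high side)")
    return brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)


def solve_fixed_point(tf: TransferFunction, J0: float, I0: float,
                      K: float = np.inf) -> DMFTFixedPoint:
    """Solve the fixed-point self-consistency for (mu, sigma).

    Nested scalar root finding: for each trial variance ``sigma`` the mean
    ``mu`` is pinned by the rate equation (monotone in mu), and the outer
    residual is ``sigma - J0^2 C_hat(mu, sigma)``.
    """
    if J0 < 0:
        raise ValueError("J0 must be non-negative")
    if J0 == 0.0:
        if np.isinf(K):
            raise ValueError("J0=0 has no balanced K->inf limit")
        mu = _mu_of_variance(tf, 0.0, I0, K, 0.0)
        return DMFTFixedPoint(mu, 0.0, tr.mean_rate(tf, mu, 0.0), J0, I0, K, tf)

    def resid(sigma):
        mu = _mu_of_variance(tf, J0, I0, K, sigma)
        return sigma - J0**2 * tr.C_hat(tf, mu, sigma)

    # the residual need not be monotone in sigma (steep power laws): scan a
    # log grid for the first (- -> +) crossing and refine it
    scale = max(J0, I0, 1.0) ** 2
    grid = scale * np.logspace(-14, 3, 160)
    prev_s, prev_r = None, None
    bracket = None
    for s in grid:
        try:
            r = resid(s)
        except (RuntimeError, OverflowError, FloatingPointError):
            break
        if prev_r is not None and prev_r < 0 <= r:
            bracket = (prev_s, s)
            break
        prev_s, prev_r = s, r
    if bracket is None:
        raise RuntimeError(
            f"no self-consistent fixed-point variance found (J0={J0}, I0={I0})")
    sigma = brentq(resid, *bracket, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    mu = _mu_of_variance(tf, J0, I0, K, sigma)
    return DMFTFixedPoint(mu, sigma, tr.mean_rate(tf, mu, sigma), J0, I0, K, tf)


def critical_coupling(tf: TransferFunction, I0: float,
                      K: float = np.inf) -> float:
    """Critical coupling J_c: J0^2 int Dz g'(mu + sqrt(sigma) z)^2 = 1
    evaluated at the self-consistent fixed point.

    Raises
    ------
    AlwaysUnstableError
        If int Dz g'^2 diverges (LIF; power law with gamma <= 1/2): the
        fixed point is predicted unstable for every J0 > 0.
    """
    if not tf.has_finite_gprime_sq or (
            tf.kind == "threshold_power" and tf.gamma <= 0.5):
        raise AlwaysUnstableError(
            "divergent g'^2 moment: fixed point unstable for all J0 > 0")

    def f(J0):
        fp = solve_fixed_point(tf, J0, I0, K)
        return J0**2 * tr.C_hat_prime(tf, fp.mu, fp.sigma) - 1.0

    # scan upward for the first sign change; steep power laws can lose the
    # fixed point altogether (fold) slightly beyond the instability, so stop
    # the scan where the fixed point ceases to exist
    lo = 1.02 * I0 if (tf.kind == "sigmoid_erf" and np.isinf(K)) else 1e-3
    grid = lo * np.logspace(0, 5, 250)
    prev_J = prev_f = None
    for J0 in grid:
        try:
            val = f(J0)
        except RuntimeError:
            break
        if prev_f is not None and prev_f < 0 <= val:
            return brentq(f, prev_J, J0, xtol=1e-13, rtol=8.9e-16, maxiter=200)
        if val >= 0 and prev_f is None:
            raise RuntimeError(
                f"fixed point already unstable at the smallest scanned J0={J0}")
        prev_J, prev_f = J0, val
    raise RuntimeError(
        "no instability crossing found before the fixed point disappears")


# ---------------------------------------------------------------------------
# potential and PAC dynamics
# ---------------------------------------------------------------------------


def potential(tf: TransferFunction, J0: float, mu: float, sigma0: float,
              sigma: float) -> PotentialEvaluation:
    """V(sigma; sigma0) = -sigma^2/2 + J0^2 <G G> and its derivative.

    V' = -sigma + J0^2 C~(sigma), so stationarity of V at sigma0 is exactly
    the fixed-point condition.
    """
    V = -0.5 * sigma**2 + J0**2 * tr.G_moment(tf, mu, sigma0, sigma)
    Vp = -sigma + J0**2 * tr.C_tilde(tf, mu, sigma0, sigma)
    return PotentialEvaluation(sigma, sigma0, mu, V, Vp)


def pac_ode_rhs(tf: TransferFunction, J0: float, mu: float, sigma0: float,
                sigma: float, tau_syn: float = 1.0) -> float:
    """tau^2 sigma'' = sigma - J0^2 C~(sigma) (= -dV/dsigma)."""
    return (sigma - J0**2 * tr.C_tilde(tf, mu, sigma0, sigma)) / tau_syn**2


def _interior_maximum(tf, J0, mu, sigma0):
    """Largest sigma < sigma0 with V'(sigma)=0 and V''<0, or None."""
    Vp = lambda s: -s + J0**2 * tr.C_tilde(tf, mu, sigma0, s)
    # grid dense near sigma0 (the chaos-onset regime lives there)
    ds = sigma0 * np.logspace(-10, 0, 240)
    grid = sigma0 - ds
    grid = grid[grid > -sigma0 * 0.999]
    vals = np.array([Vp(s) for s in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    for idx in sign_change:  # ordered from nearest-to-sigma0 downward
        a, b = grid[idx + 1], grid[idx]
        root = brentq(Vp, a, b, xtol=1e-16, rtol=8.9e-16, maxiter=200)
        h = max(1e-9 * sigma0, 1e-12)
        if Vp(root + h) - Vp(root - h) < 0:  # V'' < 0: a maximum
            return root
    return None


def solve_chaotic(tf: TransferFunction, J0: float, I0: float,
                  K: float = np.inf, tau_syn: float = 1.0,
                  n_tau: int = 600, tail_tol: float = 1e-4,
                  ) -> DMFTChaoticSolution:
    """Construct the chaotic-state solution (mu, sigma0, sigma_inf, sigma(tau)).

    Strategy: for a trial sigma0, mu follows from the rate equation; the
    candidate sigma_inf is the interior maximum of V(.; sigma0); the
    self-consistent sigma0 is the root of the energy-matching condition
    V(sigma_inf) = V(sigma0) (the PAC trajectory is the separatrix that
    creeps into the maximum as tau -> infinity).  The PAC curve is then the
    integral of tau^2 sigma'' = -V'(sigma) from (sigma0, 0), truncated when
    it reaches sigma_inf to within ``tail_tol`` of the amplitude.
    """
    fp = solve_fixed_point(tf, J0, I0, K)
    try:
        stable = J0**2 * tr.C_hat_prime(tf, fp.mu, fp.sigma) < 1.0
        if stable:
            raise NoChaoticSolution(
                f"J0={J0} is below the critical coupling at I0={I0}")
    except DivergentMomentError:
        pass  # always-unstable transfer functions: chaotic state for any J0

    def mismatch(sigma0):
        mu = _mu_of_variance(tf, J0, I0, K, sigma0)
        smax = _interior_maximum(tf, J0, mu, sigma0)
        if smax is None:
            return None
        VG = lambda s: -0.5 * s**2 + J0**2 * tr.G_moment(tf, mu, sigma0, s)
        return VG(smax) - VG(sigma0)

    # bracket in sigma0 below the fixed-point variance, stepping geometrically
    hi = fp.sigma * (1.0 - 1e-9)
    D_hi = mismatch(hi)
    if D_hi is None or D_hi <= 0:
        # retry from slightly different anchor before giving up
        hi = fp.sigma * (1.0 - 1e-6)
        D_hi = mismatch(hi)
        if D_hi is None or D_hi <= 0:
            raise NoChaoticSolution(
                f"no energy-matched PAC solution found at J0={J0}, I0={I0}")
    step = fp.sigma * 1e-8
    lo = None
    none_at = None
    while step < fp.sigma:
        cand = fp.sigma - step
        D = mismatch(cand)
        if D is None:
            none_at = cand
            break
        if D < 0:
            lo = cand
            break
        hi, D_hi = cand, D
        step *= 2.0
    if lo is None and none_at is not None:
        # the interior maximum of V disappears (fold) below some sigma0;
        # bisect between the last D>0 point and the fold for a D<0 point
        a, b = hi, none_at
        for _ in range(80):
            m = 0.5 * (a + b)
            D = mismatch(m)
            if D is None:
                b = m
            elif D < 0:
                lo = m
                break
            else:
                a = m
            if abs(a - b) < 1e-13 * fp.sigma:
                break
        hi = a
    if lo is None:
        raise NoChaoticSolution(
            f"could not bracket the self-consistent sigma0 at J0={J0}")

    sigma0 = brentq(lambda s: mismatch(s), lo, hi,
                    xtol=1e-15 * fp.sigma, rtol=8.9e-16, maxiter=200)
    mu = _mu_of_variance(tf, J0, I0, K, sigma0)
    sigma_inf = _interior_maximum(tf, J0, mu, sigma0)
    amp = sigma0 - sigma_inf

    # --- integrate the PAC ODE ---------------------------------------------
    def rhs(t, y):
        s = min(max(y[0], -sigma0), sigma0)  # RK trial stages may overshoot
        return [y[1], (s - J0**2 * tr.C_tilde(tf, mu, sigma0, s)) / tau_syn**2]

    def reach(t, y):
        return y[0] - (sigma_inf + tail_tol * amp)
    reach.terminal = True
    reach.direction = -1

    def overshoot(t, y):
        return y[0] - (sigma_inf - 0.05 * amp)
    overshoot.terminal = True
    overshoot.direction = -1

    def turnaround(t, y):
        return y[1]
    turnaround.terminal = True
    turnaround.direction = 1

    # the asymptotic approach rate to sigma_inf is omega = sqrt(|V''|)/tau
    h = 1e-4 * amp
    Vpp = (rhs(0.0, [sigma_inf - h, 0.0])[1]
           - rhs(0.0, [sigma_inf + h, 0.0])[1]) * tau_syn**2 / (2.0 * h)
    omega = np.sqrt(max(abs(Vpp), 1e-12)) / tau_syn
    t_hi = 60.0 / omega + 20.0 * tau_syn
    sol = solve_ivp(rhs, (0.0, t_hi), [sigma0, 0.0], rtol=1e-10,
                    atol=1e-13 * sigma0, events=(reach, overshoot, turnaround),
                    dense_output=True, max_step=0.25 / omega)
    t_end = sol.t[-1]
    tau_grid = np.linspace(0.0, t_end, n_tau)
    curve = sol.sol(tau_grid)[0]
    curve = np.clip(curve, sigma_inf, sigma0)

    # energy drift diagnostic: E = (tau sigma')^2/2 + V(sigma)
    VG = lambda s: -0.5 * s**2 + J0**2 * tr.G_moment(tf, mu, sigma0, s)
    idx = np.linspace(0, len(sol.t) - 1, min(25, len(sol.t))).astype(int)
    E = [0.5 * (tau_syn * sol.y[1, i])**2 + VG(sol.y[0, i]) for i in idx]
    scale = max(abs(E[0]), 0.5 * amp**2)
    drift = float(np.max(np.abs(np.asarray(E) - E[0])) / scale)

    return DMFTChaoticSolution(mu, sigma0, sigma_inf, tau_grid, curve,
                               J0, I0, K, tf, tau_syn, drift)


# ---------------------------------------------------------------------------
# fixed-point rate distribution
# ---------------------------------------------------------------------------


@dataclass
class RateDistribution:
    """Mixture law of time-averaged rates at the fixed point: an atom at zero
    (sub-threshold neurons) plus a continuous density via r = g(h)."""

    atom_mass: float
    fp: DMFTFixedPoint

    def pdf(self, r):
        """Continuous part of the density (excludes the atom)."""
        tf, mu, s = self.fp.tf, self.fp.mu, self.fp.sigma
        r = np.asarray(r, dtype=float)
        h = self._g_inv(r)
        gp = tf.g_prime(h)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.exp(-((h - mu) ** 2) / (2 * s)) / np.sqrt(2 * np.pi * s) / gp
        return np.where(np.isfinite(out) & (r > 0), out, 0.0)

    def _g_inv(self, r):
        tf = self.fp.tf
        r = np.clip(r, 1e-300, None)
        if tf.kind == "sigmoid_erf":
            from scipy.special import ndtri
            return ndtri(np.clip(r, 1e-16, 1 - 1e-16))
        if tf.kind in ("threshold_power", "threshold_linear"):
            return np.power(r, 1.0 / tf.gamma)
        return 1.0 / (1.0 - np.exp(-1.0 / (tf.tau_m * r)))


def rate_distribution_fixed_point(fp: DMFTFixedPoint) -> RateDistribution:
    """Distribution of neuronal rates at the fixed point (Gaussian input law
    pushed through g): delta at zero rate with mass P(h < threshold), plus a
    change-of-variables density above it."""
    tf = fp.tf
    if np.isfinite(tf.threshold):
        from scipy.special import ndtr
        atom = float(ndtr((tf.threshold - fp.mu) / np.sqrt(fp.sigma)))
    else:
        atom = 0.0
    return RateDistribution(atom, fp)


# ---------------------------------------------------------------------------
# critical scaling at chaos onset
# ---------------------------------------------------------------------------


def critical_asymptotics(tf: TransferFunction, I0: float,
                         deltas_rel=(0.01, 0.02, 0.05, 0.1),
                         K: float = np.inf, fit_scaling_function: bool = False):
    """Solve the chaotic theory at small distances above onset and extract
    the critical exponents of the PAC.

    Returns a dict with the amplitude exponent ``alpha`` (slope of
    log(sigma0-sigma_inf) vs log(delta)), the decorrelation-time exponent
    ``beta`` and, optionally, the universal scaling-function fit
    sigma_s(x) ~ A/cosh(x/x_dec) with x = tau sqrt(delta) (threshold-linear
    family, where the amplitude vanishes quadratically).
    """
    from ..metrics import fit_pac, PACCurve

    Jc = critical_coupling(tf, I0, K)
    family = "cosh2" if tf.kind == "sigmoid_erf" else "cosh1"
    deltas, amps, tdecs, sols = [], [], [], []
    for dr in deltas_rel:
        d = dr * Jc
        sol = solve_chaotic(tf, Jc + d, I0, K)
        pac = PACCurve(sol.tau_grid, sol.sigma_of_tau - sol.sigma_inf,
                       source="dmft")
        fit = fit_pac(pac, family=family)
        deltas.append(d)
        amps.append(sol.amplitude)
        tdecs.append(fit.tau_dec)
        sols.append(sol)
    ld, la, lt = np.log(deltas), np.log(amps), np.log(tdecs)
    alpha = float(np.polyfit(ld, la, 1)[0])
    beta = float(np.polyfit(ld, lt, 1)[0])
    out = {"Jc": Jc, "delta": np.array(deltas), "amplitude": np.array(amps),
           "tau_dec": np.array(tdecs), "alpha": alpha, "beta": beta,
           "solutions": sols}
    if fit_scaling_function:
        d, sol = deltas[0], sols[0]
        x = sol.tau_grid * np.sqrt(d)
        y = (sol.sigma_of_tau - sol.sigma_inf) / d**2
        fit = fit_pac(PACCurve(x, y, source="dmft"), family="cosh1")
        out["scaling_A"] = fit.amplitude
        out["scaling_x_dec"] = fit.tau_dec
    return out
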