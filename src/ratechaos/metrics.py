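"""Chaos metrics: autocovariance estimation, cosh-family fits, the maximum
Lyapunov exponent (Benettin resets) and the fraction-of-stable-networks scan.

The population-averaged autocovariance (PAC)

    sigma(k dt) = (1/N) sum_i <f_i(t) f_i(t+k dt)>_t - [grand mean]^2

is the central order parameter: its value at lag 0 is the total input
variance, its infinite-lag plateau the quenched variance, and its decay time
the correlation time of the chaotic fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PACCurve",
    "PACFit",
    "LyapunovEstimate",
    "StabilityFraction",
    "pac_estimate",
    "fit_pac",
    "max_lyapunov",
    "stability_fraction",
]


@dataclass
class PACCurve:
    """One-sided PAC: values at non-negative lags (sigma is even in lag)."""

    lags: np.ndarray
    values: np.ndarray
    n_samples: int = 0
    source: str = "simulation"

    @property
    def amplitude(self) -> float:
        return float(self.values[0] - self.values[-1])


def pac_estimate(traces: np.ndarray, dt: float, max_lag: float,
                 source: str = "simulation") -> PACCurve:
    """Population-averaged autocovariance of per-neuron traces.

    Parameters
    ----------
    traces : (n_neurons, n_samples) array
        Stationary segment (transient already removed).
    dt : float
        Sampling interval of the traces.
    max_lag : float
        Largest lag to return; must be shorter than the record.

    Notes
    -----
    Lag-k products are averaged over the ``n_samples - k`` available pairs
    (per the estimator's printed divisor) and over neurons; the squared grand
    mean over neurons and time is subtracted once.
    """
    f = np.asarray(traces, dtype=float)
    if f.ndim != 2:
        raise ValueError("traces must be 2-D (neurons x time)")
    n, nt = f.shape
    kmax = int(round(max_lag / dt))
    if kmax >= nt:
        raise ValueError(f"max_lag={max_lag} exceeds record length {nt * dt}")
    nfft = 1 << int(np.ceil(np.log2(2 * nt)))
    F = np.fft.rfft(f, n=nfft, axis=1)
    acf = np.fft.irfft((F * np.conj(F)).sum(axis=0), n=nfft)[: kmax + 1]
    acf /= n * (nt - np.arange(kmax + 1))
    grand = f.mean()
    return PACCurve(np.arange(kmax + 1) * dt, acf - grand**2, nt, source)


@dataclass
class PACFit:
    amplitude: float
    tau_dec: float
    offset: float
    residual: float
    family: str


def _sech(x):
    # overflow-safe 1/cosh
    ax = np.abs(x)
    e = np.exp(-ax)
    return 2.0 * e / (1.0 + e * e)


_FAMILIES = {
    "cosh1": lambda t, A, td: A * _sech(t / td),
    "cosh2": lambda t, A, td: A * _sech(t / td) ** 2,
}


def fit_pac(pac: PACCurve, family: str = "cosh1") -> PACFit:
    """Nonlinear least-squares fit of a decaying PAC to a cosh family.

    ``cosh1``: A/cosh(tau/tau_dec); ``cosh2``: A/cosh^2; ``cosh1_offset``:
    B + A/cosh.  The initial guess comes from the half-width at
    half-amplitude; lags where the curve has decayed below 2% of the
    amplitude are excluded (tail noise).
    """
    t, y = np.asarray(pac.lags, float), np.asarray(pac.values, float)
    offset = 0.0
    base = family
    if family == "cosh1_offset":
        offset = float(np.min(y))
        y = y - offset
        base = "cosh1"
    if base not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    A0 = float(y[0])
    if A0 <= 0 or not np.any(y < 0.5 * A0):
        raise RuntimeError("PAC does not decay: no decorrelation time")
    ihalf = int(np.argmax(y < 0.5 * A0))
    td0 = max(t[ihalf], t[1] if len(t) > 1 else 1.0)
    keep = y > 0.02 * A0
    keep[0] = True
    fun = _FAMILIES[base]
    popt, _ = curve_fit(fun, t[keep], y[keep], p0=[A0, td0], maxfev=20000)
    A, td = float(popt[0]), float(abs(popt[1]))
    resid = float(np.sqrt(np.mean((fun(t[keep], A, td) - y[keep]) ** 2)) / A)
    if family == "cosh1_offset":
        return PACFit(A, td, offset, resid, family)
    return PACFit(A, td, 0.0, resid, family)


# ---------------------------------------------------------------------------
# maximum Lyapunov exponent (Benettin renormalization)
# ---------------------------------------------------------------------------


@dataclass
class LyapunovEstimate:
    Lambda: float            # 1 / time-unit of the dynamics object
    n_resets: int
    T_max: float
    D_max: float
    epsilon: float
    seed: int | None = None
    reset_times: np.ndarray | None = None
    reset_dists: np.ndarray | None = None


def max_lyapunov(dynamics, tau_ref: float, n_resets: int = 100,
                 T_max: float | None = None, D_max: float = 1e-3,
                 epsilon: float = 1e-6, transient: float | None = None,
                 seed: int | None = None) -> LyapunovEstimate:
    """Benettin estimate of the maximum Lyapunov exponent of a flow.

    ``dynamics`` must expose ``state`` (1-D float array, writable),
    ``advance(T)`` and ``copy()``.  After a transient (default 200 tau_ref)
    a twin copy is displaced by ``epsilon/sqrt(dim)`` per component
    (l2 distance epsilon); the pair is integrated until the separation first
    reaches ``D_max`` or for at most ``T_max`` (default 5 tau_ref),
    whichever comes first; the twin is then re-placed at distance epsilon
    along the current separation and the cycle repeats, giving

        Lambda = sum_i ln(D_reset_i / epsilon) / sum_i T_reset_i.

    Segments in which the separation shrinks contribute their (negative)
    logarithm as well.
    """
    if T_max is None:
        T_max = 5.0 * tau_ref
    if transient is None:
        transient = 200.0 * tau_ref
    if transient > 0:
        dynamics.advance(transient)
    twin = dynamics.copy()
    dim = dynamics.state.size
    twin.state[:] = dynamics.state + epsilon / np.sqrt(dim)

    check = max(tau_ref / 20.0, getattr(dynamics, "dt", tau_ref / 20.0))
    paired = hasattr(dynamics, "advance_pair")
    logs, times = [], []
    for _ in range(n_resets):
        t_seg = 0.0
        while True:
            step = min(check, T_max - t_seg)
            if paired:
                dynamics.advance_pair(twin, step)
            else:
                dynamics.advance(step)
                twin.advance(step)
            t_seg += step
            d = twin.state - dynamics.state
            D = float(np.linalg.norm(d))
            if D >= D_max or t_seg >= T_max - 1e-12:
                break
        if not np.isfinite(D) or D == 0.0:
            raise FloatingPointError("separation vanished or diverged")
        logs.append(np.log(D / epsilon))
        times.append(t_seg)
        twin.state[:] = dynamics.state + d * (epsilon / D)
    logs, times = np.asarray(logs), np.asarray(times)
    return LyapunovEstimate(float(logs.sum() / times.sum()), n_resets,
                            T_max, D_max, epsilon, seed, times, logs)


# ---------------------------------------------------------------------------
# fraction of networks with an unstable fixed point
# ---------------------------------------------------------------------------


@dataclass
class StabilityFraction:
    J0_grid: np.ndarray
    fraction_unstable: np.ndarray      # percent
    J_m: float                         # logistic midpoint
    Delta_J: float                     # logistic width
    residual: float

    def J_at(self, percent: float) -> float:
        """Coupling at which the fitted unstable fraction equals ``percent``."""
        p = percent / 100.0
        return self.J_m + self.Delta_J * np.log(p / (1.0 - p))


def _logistic(J, Jm, dJ):
    return 100.0 / (1.0 + np.exp(-(J - Jm) / dJ))


def stability_fraction(tf, J0_grid, I0, N, K, n_realizations: int = 100,
                       transient: float = 256.0, duration: float = 64.0,
                       rho_threshold: float = 1e-9, dt: float = 0.05,
                       seed: int = 0) -> StabilityFraction:
    """Fraction of connectivity realizations whose rate dynamics do NOT reach
    a fixed point, as a function of J0, with a logistic fit.

    A realization counts as unstable when the population-averaged temporal
    variance of the inputs, rho, exceeds ``rho_threshold`` after discarding
    a transient (times in units of tau_syn).
    """
    from .network import NetworkParams, sample_connectivity, simulate_rate_onepop

    J0_grid = np.asarray(J0_grid, dtype=float)
    frac = np.empty_like(J0_grid)
    rng = np.random.default_rng(seed)
    for jdx, J0 in enumerate(J0_grid):
        unstable = 0
        for _ in range(n_realizations):
            s = int(rng.integers(2**31 - 1))
            params = NetworkParams(N=N, K=K, J0=float(J0), I0=I0, tau=1.0,
                                   tf=tf, seed=s)
            C = sample_connectivity(N, K, seed=s)
            traj = simulate_rate_onepop(
                params, C, T=transient + duration, dt=dt,
                record_start=transient, record_stride=max(1, int(0.2 / dt)))
            rho = float(np.mean(np.var(traj.h, axis=1)))
            unstable += rho > rho_threshold
        frac[jdx] = 100.0 * unstable / n_realizations
    if np.all(frac == 0.0) or np.all(frac == 100.0):
        return StabilityFraction(J0_grid, frac, np.nan, np.nan, np.nan)
    p0 = [J0_grid[np.argmin(np.abs(frac - 50.0))],
          0.25 * (J0_grid[-1] - J0_grid[0]) + 1e-3]
    popt, _ = curve_fit(_logistic, J0_grid, frac, p0=p0, maxfev=20000)
    resid = float(np.sqrt(np.mean((_logistic(J0_grid, *popt) - frac) ** 2)))
    return StabilityFraction(J0_grid, frac, float(popt[0]), float(abs(popt[1])),
                             resid)
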