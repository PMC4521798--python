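"""Neuronal transfer functions and the Gaussian calculus built on them.

The mean-field description of a sparsely connected balanced network reduces
every network-level quantity to Gaussian integrals of the single-neuron
transfer function g (the f-I curve), of its derivative g', and of its
antiderivative G.  This module provides the four transfer-function families
used throughout the package

* ``sigmoid_erf``       g(x) = phi(x) = [1 + erf(x/sqrt(2))]/2
* ``threshold_power``   g(x) = x**gamma * H(x)        (gamma > 0)
* ``threshold_linear``  g(x) = x * H(x)               (gamma = 1)
* ``lif``               g(x) = -1/(tau_m * ln(1 - 1/x)) * H(x - 1)

together with the Gaussian moments that the self-consistency equations are
made of.  Closed forms are used wherever they exist (erf/Owen's-T identities
for the sigmoid, truncated-Gaussian moments for the power-law family) and
Gauss-Hermite quadrature otherwise.

Conventions
-----------
``Dz`` denotes the standard normal measure.  All "smoothed" quantities are
means over an independent Gaussian of variance ``v``::

    m_g(a, v)  = int g (a + sqrt(v) xi) Dxi
    m_gp(a, v) = int g'(a + sqrt(v) xi) Dxi
    m_G(a, v)  = int G (a + sqrt(v) xi) Dxi

For the LIF transfer function the natural time unit is the membrane time
constant; with ``tau_m=1`` the returned rates are in units of 1/tau_m
(multiply by 1/tau_m in seconds to get Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy import sqrt, exp, pi
from scipy import special
from scipy.integrate import quad
from scipy.interpolate import InterpolatedUnivariateSpline

__all__ = [
    "TransferFunction",
    "DivergentMomentError",
    "sigmoid_erf",
    "threshold_power",
    "threshold_linear",
    "lif",
    "from_name",
    "gauss_mean",
    "mean_rate",
    "smoothed_g",
    "smoothed_gprime",
    "smoothed_G",
    "C_hat",
    "C_hat_prime",
    "C_tilde",
    "C_tilde_prime",
    "G_moment",
    "truncated_moments",
    "trunc_power_moment",
]

_SQRT2PI = sqrt(2.0 * pi)


class DivergentMomentError(ArithmeticError):
    """A Gaussian moment diverges (e.g. int Dz g'(..)^2 for the LIF f-I curve).

    This is semantically meaningful: when the second moment of g' diverges the
    mean-field fixed point is unstable at any coupling strength.
    """


# ---------------------------------------------------------------------------
# Gauss-Hermite machinery (probabilists' convention: weight e^{-z^2/2})
# ---------------------------------------------------------------------------

_gh_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def gh_nodes(n: int = 201) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights such that sum w_k f(z_k) ~ int f(z) Dz."""
    if n not in _gh_cache:
        z, w = np.polynomial.hermite_e.hermegauss(n)
        _gh_cache[n] = (z, w / _SQRT2PI)
    return _gh_cache[n]


_gl_cache: dict = {}


def _gl_panels(edges: tuple, n: int = 120) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights tiled over the panels between ``edges``."""
    key = (edges, n)
    if key not in _gl_cache:
        if "base" not in _gl_cache:
            _gl_cache["base"] = np.polynomial.legendre.leggauss(n)
        x, w = _gl_cache["base"]
        zs, ws = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            zs.append(0.5 * (b - a) * x + 0.5 * (a + b))
            ws.append(0.5 * (b - a) * w)
        if len(_gl_cache) > 4096:   # keep the cache bounded
            _gl_cache.clear()
        _gl_cache[key] = (np.concatenate(zs), np.concatenate(ws))
    return _gl_cache[key]


def _phi(x):
    """Standard normal CDF."""
    return special.ndtr(x)


def _phip(x):
    """Standard normal PDF."""
    return exp(-0.5 * np.square(x)) / _SQRT2PI


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferFunction:
    """A neuronal f-I curve g(h), with derivative and antiderivative.

    Attributes
    ----------
    kind : str
        One of ``sigmoid_erf``, ``threshold_power``, ``threshold_linear``,
        ``lif``.
    gamma : float
        Exponent of the power-law family (1.0 for threshold_linear).
    tau_m : float
        Membrane time constant (LIF only), in the chosen time unit.
    threshold : float
        g(x) == 0 for x <= threshold (-inf for the sigmoid).
    """

    kind: str
    gamma: float = 1.0
    tau_m: float = 1.0
    threshold: float = -np.inf
    # lazily built LIF antiderivative spline; dataclass is frozen so use a box
    _G_spline: list = field(default_factory=list, repr=False, compare=False)

    # -- pointwise evaluation ------------------------------------------------

    def g(self, x):
        """Firing rate at net input ``x`` (exactly 0 at/below threshold)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "sigmoid_erf":
            return _phi(x)
        if self.kind in ("threshold_power", "threshold_linear"):
            out = np.where(x > 0.0, np.power(np.clip(x, 0.0, None), self.gamma), 0.0)
            return out if out.ndim else float(out)
        # lif: g -> 0 as x -> 1+ (continuously), g ~ x/tau_m for large x
        xc = np.clip(x, 1.0 + 1e-300, None)
        with np.errstate(divide="ignore"):
            val = -1.0 / (self.tau_m * np.log1p(-1.0 / xc))
        out = np.where(x > 1.0, val, 0.0)
        return out if out.ndim else float(out)

    def g_prime(self, x):
        """dg/dx; at a threshold the left limit (0) is used."""
        x = np.asarray(x, dtype=float)
        if self.kind == "sigmoid_erf":
            return _phip(x)
        if self.kind in ("threshold_power", "threshold_linear"):
            g = self.gamma
            with np.errstate(divide="ignore", invalid="ignore"):
                val = g * np.power(np.clip(x, 0.0, None), g - 1.0)
            out = np.where(x > 0.0, val, 0.0)
            return out if out.ndim else float(out)
        xc = np.clip(x, 1.0 + 1e-300, None)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            L = np.log1p(-1.0 / xc)
            val = 1.0 / (self.tau_m * L * L * xc * (xc - 1.0))
        out = np.where(x > 1.0, val, 0.0)
        return out if out.ndim else float(out)

    def G(self, x):
        """Antiderivative of g anchored at the threshold (G(threshold)=0).

        For the sigmoid, G(x) = Phi(x) = x phi(x) + N'(x); closed forms exist
        for the power-law family; the LIF case uses a cached adaptive
        quadrature (the integrand has an integrable singularity-free form but
        no elementary antiderivative).
        """
        x = np.asarray(x, dtype=float)
        if self.kind == "sigmoid_erf":
            return x * _phi(x) + _phip(x)
        if self.kind in ("threshold_power", "threshold_linear"):
            g1 = self.gamma + 1.0
            out = np.where(x > 0.0, np.power(np.clip(x, 0.0, None), g1) / g1, 0.0)
            return out if out.ndim else float(out)
        spline, x_hi = self._lif_G_spline()
        out = np.where(
            x <= 1.0,
            0.0,
            np.where(x <= x_hi, spline(np.clip(x, 1.0, x_hi)), 0.0),
        )
        big = x > x_hi
        if np.any(big):
            # g(x) = x/tau_m - 1/(2 tau_m) + O(1/x): integrate the asymptote
            xb = np.asarray(x)[big]
            out = np.asarray(out)
            out[big] = spline(x_hi) + (0.5 * (xb**2 - x_hi**2) - 0.5 * (xb - x_hi)) / self.tau_m
        return out if out.ndim else float(out)

    def _lif_G_spline(self):
        if not self._G_spline:
            xg = 1.0 + np.logspace(-12, np.log10(199.0), 1500)
            vals = np.empty_like(xg)
            acc = 0.0
            lo = 1.0
            for i, hi in enumerate(xg):
                acc += quad(self.g, lo, hi, limit=200)[0]
                vals[i] = acc
                lo = hi
            sp = InterpolatedUnivariateSpline(xg, vals, k=3, ext=3)
            self._G_spline.append((sp, float(xg[-1])))
        return self._G_spline[0]

    # -- metadata ------------------------------------------------------------

    @property
    def has_finite_gprime_sq(self) -> bool:
        """Whether int Dz g'(mu + s z)^2 converges.

        Diverges for the LIF curve (g' blows up at threshold like
        1/((x-1) ln^2(x-1))) and for power laws with gamma < 1/2.
        """
        if self.kind == "lif":
            return False
        if self.kind == "threshold_power":
            return self.gamma >= 0.5  # gamma = 1/2 is marginally divergent too
        return True


def sigmoid_erf() -> TransferFunction:
    return TransferFunction("sigmoid_erf")


def threshold_power(gamma: float) -> TransferFunction:
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return TransferFunction("threshold_power", gamma=gamma, threshold=0.0)


def threshold_linear() -> TransferFunction:
    return TransferFunction("threshold_linear", gamma=1.0, threshold=0.0)


def lif(tau_m: float = 1.0) -> TransferFunction:
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    return TransferFunction("lif", tau_m=tau_m, threshold=1.0)


def from_name(name: str, **params) -> TransferFunction:
    """Build a transfer function from a config-style name."""
    table = {
        "sigmoid_erf": sigmoid_erf,
        "sigmoid": sigmoid_erf,
        "threshold_power": threshold_power,
        "threshold_linear": threshold_linear,
        "lif": lif,
    }
    if name not in table:
        raise ValueError(f"unknown transfer function {name!r}")
    return table[name](**params)


# ---------------------------------------------------------------------------
# Truncated Gaussian moments
# ---------------------------------------------------------------------------


def trunc_power_moment(p: float, u):
    """M_p(u) = E[(u + Z)^p H(u + Z)] for Z ~ N(0, 1) and p > -1.

    Closed form via the parabolic cylinder function:
    M_p(u) = Gamma(p+1) e^{-u^2/4} D_{-p-1}(-u) / sqrt(2 pi).
    Integer p in {0, 1, 2, 3} use elementary expressions.
    """
    if p <= -1:
        raise DivergentMomentError(f"truncated moment of order {p} diverges")
    u = np.asarray(u, dtype=float)
    if p == 0:
        out = _phi(u)
        return out if out.ndim else float(out)
    if p == 1:
        out = u * _phi(u) + _phip(u)
        return out if out.ndim else float(out)
    if p == 2:
        out = (u * u + 1.0) * _phi(u) + u * _phip(u)
        return out if out.ndim else float(out)
    if p == 3:
        out = u * (u * u + 3.0) * _phi(u) + (u * u + 2.0) * _phip(u)
        return out if out.ndim else float(out)
    out = np.empty_like(u, dtype=float)
    lo = u < -12.0
    hi = u > 12.0
    mid = ~(lo | hi)
    out[lo] = 0.0
    if np.any(hi):
        # effectively untruncated: asymptotic expansion of E[(u+Z)^p]
        ub = u[hi]
        out[hi] = np.power(ub, p) * (
            1.0
            + p * (p - 1.0) / (2.0 * ub**2)
            + p * (p - 1.0) * (p - 2.0) * (p - 3.0) / (8.0 * ub**4)
        )
    if np.any(mid):
        um = u[mid]
        dv = np.array([special.pbdv(-p - 1.0, -x)[0] for x in np.atleast_1d(um)])
        out[mid] = special.gamma(p + 1.0) * exp(-um * um / 4.0) * dv / _SQRT2PI
    return out if out.ndim else float(out)


def truncated_moments(mu, sigma):
    """First two moments of the rectified Gaussian, (F1, F2).

    F1 = E[(mu + sqrt(sigma) z) H(.)], F2 = E[(mu + sqrt(sigma) z)^2 H(.)].
    These are the mean rate and rate second moment of a threshold-linear
    population with Gaussian input of mean ``mu`` and variance ``sigma``.
    """
    mu = np.asarray(mu, dtype=float)
    s = sqrt(sigma)
    u = mu / s
    F1 = mu * _phi(u) + s * _phip(u)
    F2 = (mu * mu + sigma) * _phi(u) + mu * s * _phip(u)
    return F1, F2


# ---------------------------------------------------------------------------
# Gaussian means of g, g', G  (vectorized over the location argument)
# ---------------------------------------------------------------------------


def gauss_mean(f: Callable, mu: float, sigma2: float, n_nodes: int = 201) -> float:
    """int f(mu + sqrt(sigma2) z) Dz by Gauss-Hermite quadrature.

    Generic entry point for arbitrary integrands; the moments with known
    closed forms go through the specialised functions below.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if sigma2 == 0.0:
        return float(f(mu))
    z, w = gh_nodes(n_nodes)
    return float(np.sum(w * f(mu + sqrt(sigma2) * z)))


def smoothed_g(tf: TransferFunction, a, v: float):
    """m_g(a, v) = int g(a + sqrt(v) xi) Dxi, vectorized over ``a``."""
    a = np.asarray(a, dtype=float)
    if v < 0:
        if v > -1e-12:
            v = 0.0
        else:
            raise ValueError("variance must be non-negative")
    if v == 0.0:
        return tf.g(a)
    if tf.kind == "sigmoid_erf":
        return _phi(a / sqrt(1.0 + v))
    if tf.kind in ("threshold_linear", "threshold_power"):
        if tf.gamma == 1.0:
            return truncated_moments(a, v)[0]
        if tf.gamma == 2.0:
            return truncated_moments(a, v)[1]
        return v ** (tf.gamma / 2.0) * trunc_power_moment(tf.gamma, a / sqrt(v))
    z, w = gh_nodes(201)
    return np.sum(w * tf.g(a[..., None] + sqrt(v) * z), axis=-1)


def smoothed_gprime(tf: TransferFunction, a, v: float):
    """m_g'(a, v) = int g'(a + sqrt(v) xi) Dxi."""
    a = np.asarray(a, dtype=float)
    if v == 0.0:
        return tf.g_prime(a)
    if tf.kind == "sigmoid_erf":
        return _phip(a / sqrt(1.0 + v)) / sqrt(1.0 + v)
    if tf.kind in ("threshold_linear", "threshold_power"):
        if tf.gamma == 1.0:
            return _phi(a / sqrt(v))
        p = tf.gamma - 1.0
        if p <= -1.0:
            raise DivergentMomentError("mean of g' diverges for gamma <= 0")
        return tf.gamma * v ** (p / 2.0) * trunc_power_moment(p, a / sqrt(v))
    # LIF: g' has an integrable divergence at threshold; mean is finite.
    scalar = a.ndim == 0
    a1 = np.atleast_1d(a)
    out = np.empty_like(a1)
    s = sqrt(v)
    for i, ai in enumerate(a1):
        zc = (1.0 - ai) / s  # threshold location in z
        out[i] = quad(
            lambda z: tf.g_prime(ai + s * z) * _phip(z),
            zc, zc + 30.0, limit=400, points=[zc],
        )[0] if zc > -30.0 else quad(
            lambda z: tf.g_prime(ai + s * z) * _phip(z), -30.0, 30.0, limit=400
        )[0]
    return float(out[0]) if scalar else out


def smoothed_G(tf: TransferFunction, a, v: float):
    """m_G(a, v) = int G(a + sqrt(v) xi) Dxi."""
    a = np.asarray(a, dtype=float)
    if v < 0 and v > -1e-12:
        v = 0.0
    if v == 0.0:
        return tf.G(a)
    if tf.kind == "sigmoid_erf":
        # E[Phi(a + sqrt(v) xi)] = sqrt(1+v) Phi(a / sqrt(1+v))
        s = sqrt(1.0 + v)
        return s * (a / s * _phi(a / s) + _phip(a / s))
    if tf.kind in ("threshold_linear", "threshold_power"):
        g1 = tf.gamma + 1.0
        if tf.gamma == 1.0:
            return truncated_moments(a, v)[1] / 2.0
        return v ** (g1 / 2.0) * trunc_power_moment(g1, a / sqrt(v)) / g1
    z, w = gh_nodes(201)
    return np.sum(w * tf.G(a[..., None] + sqrt(v) * z), axis=-1)


# ---------------------------------------------------------------------------
# Second moments: C-hat, C-tilde and friends
# ---------------------------------------------------------------------------


def C_hat(tf: TransferFunction, mu: float, sigma: float):
    """int Dz g(mu + sqrt(|sigma|) z)^2 — second moment of the rates."""
    s = abs(sigma)
    if tf.kind == "sigmoid_erf":
        if s == 0.0:
            return float(_phi(mu) ** 2)
        # E[phi(a+bz)^2] = BvN CDF = Phi(at) - 2 T(at, 1/sqrt(1+2 b^2))
        at = mu / sqrt(1.0 + s)
        return float(_phi(at) - 2.0 * special.owens_t(at, 1.0 / sqrt(1.0 + 2.0 * s)))
    if tf.kind in ("threshold_linear", "threshold_power"):
        if s == 0.0:
            return float(tf.g(mu) ** 2)
        if tf.gamma == 1.0:
            return float(truncated_moments(mu, s)[1])
        return float(s**tf.gamma * trunc_power_moment(2.0 * tf.gamma, mu / sqrt(s)))
    if s == 0.0:
        return float(tf.g(mu) ** 2)
    sq = sqrt(s)
    zc = (1.0 - mu) / sq
    lo = max(zc, -30.0)
    if lo >= 30.0:
        return 0.0
    return quad(lambda z: tf.g(mu + sq * z) ** 2 * _phip(z), lo, 30.0, limit=400)[0]


def C_hat_prime(tf: TransferFunction, mu: float, sigma: float):
    """int Dz g'(mu + sqrt(|sigma|) z)^2 — what the chaos threshold is made of.

    Raises
    ------
    DivergentMomentError
        For the LIF curve (always) and power laws with gamma < 1/2; in those
        regimes the mean-field fixed point is unstable at any J0 > 0.
    """
    if not tf.has_finite_gprime_sq:
        raise DivergentMomentError(
            f"int Dz g'^2 diverges for {tf.kind}"
            + (f" (gamma={tf.gamma})" if tf.kind == "threshold_power" else "")
        )
    s = abs(sigma)
    if tf.kind == "sigmoid_erf":
        return float(exp(-mu * mu / (1.0 + 2.0 * s)) / (2.0 * pi * sqrt(1.0 + 2.0 * s)))
    # threshold power, gamma >= 1/2 (gamma=1/2 itself diverges: 2g-2 = -1)
    if tf.gamma == 0.5:
        raise DivergentMomentError("gamma = 1/2 is marginal: int Dz g'^2 diverges")
    if s == 0.0:
        return float(tf.g_prime(mu) ** 2)
    if tf.gamma == 1.0:
        return float(_phi(mu / sqrt(s)))
    p = 2.0 * tf.gamma - 2.0
    return float(tf.gamma**2 * s ** (tf.gamma - 1.0) * trunc_power_moment(p, mu / sqrt(s)))


def _paired_outer(tf, mu, sigma0, sigma, inner):
    """int Dz m(mu + sqrt|s| z, v) m(mu + sign(s) sqrt|s| z, v), v = s0 - |s|."""
    s = float(sigma)
    v = sigma0 - abs(s)
    if v < -1e-9 * max(1.0, sigma0):
        raise ValueError(f"|sigma|={abs(s)} exceeds sigma0={sigma0}")
    v = max(v, 0.0)
    if abs(s) == 0.0:
        return float(inner(tf, np.asarray(mu), v) ** 2)
    b = sqrt(abs(s))
    if np.isfinite(tf.threshold) and v < 0.1 * max(sigma0, 1e-12):
        # near-degenerate smoothing: the inner mean is (almost) g itself and
        # the integrand keeps a kink at the threshold, where Gauss-Hermite
        # converges slowly -> panelled Gauss-Legendre split at the kink(s)
        zc = (tf.threshold - mu) / b
        edges = [-10.0] + sorted(
            x for x in ((zc, -zc) if s < 0.0 else (zc,)) if -10.0 < x < 10.0
        ) + [10.0]
        zs, ws = _gl_panels(tuple(edges))
        m1 = inner(tf, mu + b * zs, v)
        m2 = inner(tf, mu - b * zs, v) if s < 0.0 else m1
        return float(np.sum(ws * _phip(zs) * m1 * m2))
    z, w = gh_nodes(201)
    m1 = inner(tf, mu + b * z, v)
    if s >= 0.0:
        return float(np.sum(w * m1 * m1))
    m2 = inner(tf, mu - b * z, v)  # = m1 evaluated at -z; kept explicit
    return float(np.sum(w * m1 * m2))


def C_tilde(tf: TransferFunction, mu: float, sigma0: float, sigma: float):
    """Rate autocovariance functional C~(sigma) of the mean-field theory.

    Equals int Dz [int Dxi g(mu + sqrt(sigma0-|sigma|) xi + sqrt(|sigma|) z)]^2
    for sigma >= 0 (the sign(sigma) branch handles sigma < 0).  At
    sigma = sigma0 it reduces to C_hat(mu, sigma0); at sigma = 0 it factorizes
    into the squared mean rate.
    """
    return _paired_outer(tf, mu, sigma0, sigma, smoothed_g)


def C_tilde_prime(tf: TransferFunction, mu: float, sigma0: float, sigma: float):
    """dC~/dsigma = int Dz [int Dxi g'(...)]^2 (sigma >= 0 branch)."""
    return _paired_outer(tf, mu, sigma0, sigma, smoothed_gprime)


def G_moment(tf: TransferFunction, mu: float, sigma0: float, sigma: float):
    """int Dz m_G(mu + sqrt|s| z, s0-|s|) m_G(mu + sign(s) sqrt|s| z, s0-|s|).

    The G-G correlation entering the potential V(sigma; sigma0).
    """
    return _paired_outer(tf, mu, sigma0, sigma, smoothed_G)


def mean_rate(tf: TransferFunction, mu: float, sigma: float):
    """Population mean rate int Dz g(mu + sqrt(sigma) z)."""
    if tf.kind == "lif":
        s = abs(sigma)
        if s == 0.0:
            return float(tf.g(mu))
        sq = sqrt(s)
        zc = (1.0 - mu) / sq
        lo = max(zc, -30.0)
        if lo >= 30.0:
            return 0.0
        return quad(lambda z: tf.g(mu + sq * z) * _phip(z), lo, 30.0, limit=400)[0]
    return float(smoothed_g(tf, np.asarray(mu, dtype=float), abs(sigma)))
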