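"""Stability spectra of the mean-field fixed point.

Linearizing the one-population rate dynamics about a fixed point h0 gives
delta-h' = (-I + M) delta-h / tau with the sparse random matrix

    M_ij = -(J0 / sqrt(K)) C_ij g'(h0_j),

so the fixed point destabilizes when the largest real part of an eigenvalue
of M crosses 1.  In the limit 1 << K << N the entries of M are uncorrelated
with second moment J0^2 E[g'^2]/N-ish scaling such that the bulk fills a
disk of radius

    lambda_max = J0 sqrt( int Dz g'(mu + sqrt(sigma) z)^2 )

uniformly — the conjecture verified here.  This radius equals 1 exactly at
the mean-field critical coupling.  An isolated large negative outlier of
order sqrt(K) J0 E[g'] accompanies the bulk (the mean of the entries is
non-zero and negative).

The two-population composite matrix (for J0^EE = 0)

    M = (J0^II/sqrt(K)) C~II + (J0^IE J0^EI / K) C~IE C~EI,
    C~ab_ij = g'(h0_j^b) C^ab_ij,

has the conjectured largest real eigenvalue
sqrt((J0^II)^2 C'_I + (J0^EI J0^IE)^2 C'_E C'_I), again 1 at onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import transfer as tr
from .transfer import TransferFunction
from .network import Connectivity
from .dmft.onepop import DMFTFixedPoint
from .dmft.twopop import TwoPopMeanField

__all__ = [
    "StabilityMatrix",
    "SpectrumResult",
    "build_stability_matrix",
    "build_twopop_stability_matrix",
    "spectrum",
    "lambda_max_predicted",
    "sample_fixed_point_inputs",
]


@dataclass
class StabilityMatrix:
    M: sp.spmatrix
    h0: np.ndarray | dict
    J0: float | np.ndarray
    K: int
    tf: TransferFunction


@dataclass
class SpectrumResult:
    eigenvalues: np.ndarray           # bulk sample (complex)
    lambda_max_observed: float        # largest real part
    outlier: float | None             # isolated negative eigenvalue, if found
    radial_bins: np.ndarray | None = None
    radial_density: np.ndarray | None = None   # N_eig / R per bin


def sample_fixed_point_inputs(fp: DMFTFixedPoint, N: int, seed: int = 0
                              ) -> np.ndarray:
    """Draw h0_i from the fixed-point Gaussian N(mu, sigma)."""
    rng = np.random.default_rng(seed)
    return fp.mu + np.sqrt(fp.sigma) * rng.normal(size=N)


def build_stability_matrix(h0: np.ndarray, C: Connectivity, J0: float,
                           K: int, tf: TransferFunction) -> StabilityMatrix:
    """M = -(J0/sqrt(K)) C diag(g'(h0)); instability at max Re lambda = 1."""
    M = C.matrix
    if M.shape[1] != h0.size:
        raise ValueError("h0 length does not match connectivity")
    gp = tf.g_prime(h0)
    scaled = M @ sp.diags(-J0 / np.sqrt(K) * gp)
    return StabilityMatrix(scaled.tocsr(), h0, J0, K, tf)


def build_twopop_stability_matrix(h0_E: np.ndarray, h0_I: np.ndarray,
                                  C: Connectivity, J0, K: int,
                                  tf: TransferFunction) -> StabilityMatrix:
    """Composite two-population matrix (J0^EE = 0 reduction):
    M = (J0^II/sqrt(K)) C~II + (J0^IE J0^EI / K) C~IE C~EI."""
    J0 = np.asarray(J0, dtype=float)
    if J0[0, 0] != 0.0:
        raise ValueError("composite reduction requires J0^EE = 0")
    gpE = sp.diags(tf.g_prime(h0_E))
    gpI = sp.diags(tf.g_prime(h0_I))
    sK = np.sqrt(K)
    M = (J0[1, 1] / sK) * (C.blocks["II"] @ gpI) \
        + (J0[1, 0] * J0[0, 1] / K) * (C.blocks["IE"] @ gpE) \
        @ (C.blocks["EI"] @ gpI)
    return StabilityMatrix(M.tocsr(), {"E": h0_E, "I": h0_I}, J0, K, tf)


def spectrum(sm: StabilityMatrix, n_extreme: int = 6,
             full_if_below: int = 4000, n_radial_bins: int = 40
             ) -> SpectrumResult:
    """Eigenvalues of the stability matrix.

    Dense diagonalization below ``full_if_below``; otherwise ARPACK for the
    eigenvalues of largest real part plus the most-negative outlier.  The
    radial histogram (counts divided by R, flat for a uniform disk) is
    computed from the bulk when the full spectrum is available.
    """
    M = sm.M
    N = M.shape[0]
    if N <= full_if_below:
        ev = np.linalg.eigvals(M.toarray())
        lmax = float(ev.real.max())
        outlier = float(ev.real.min())
        bulk = ev[ev.real > outlier * 0.5] if outlier < -1.0 else ev
        r = np.abs(bulk)
        edges = np.linspace(0.0, r.max() * 1.05, n_radial_bins + 1)
        counts, _ = np.histogram(r, bins=edges)
        mid = 0.5 * (edges[:-1] + edges[1:])
        return SpectrumResult(ev, lmax, outlier, mid, counts / np.maximum(mid, 1e-12))
    try:
        ev_hi = spla.eigs(M, k=n_extreme, which="LR",
                          return_eigenvectors=False, maxiter=5000)
    except spla.ArpackNoConvergence as err:
        ev_hi = err.eigenvalues
        if ev_hi is None or len(ev_hi) == 0:
            raise
    ev_lo = spla.eigs(M, k=1, which="SR", return_eigenvectors=False,
                      maxiter=5000)
    lmax = float(ev_hi.real.max())
    return SpectrumResult(np.concatenate([ev_hi, ev_lo]), lmax,
                          float(ev_lo.real.min()))


def lambda_max_predicted(tf: TransferFunction,
                         state: DMFTFixedPoint | TwoPopMeanField) -> float:
    """Conjectured largest real eigenvalue of the stability matrix.

    One population: J0 sqrt(Chat'(mu, sigma)).  Two populations (EE = 0):
    sqrt((J0^II)^2 C'_I + (J0^EI J0^IE)^2 C'_E C'_I).  Equals 1 exactly at
    the mean-field instability.

    Raises
    ------
    DivergentMomentError
        When int Dz g'^2 diverges (always-unstable regime).
    """
    if isinstance(state, DMFTFixedPoint):
        return state.J0 * np.sqrt(tr.C_hat_prime(tf, state.mu, state.sigma))
    J0 = np.asarray(state.J0, dtype=float)
    CpE = tr.C_hat_prime(tf, state.mu_E, state.sigma_E) \
        if np.isfinite(state.mu_E) else 0.0
    CpI = tr.C_hat_prime(tf, state.mu_I, state.sigma_I)
    return float(np.sqrt(J0[1, 1] ** 2 * CpI
                         + (J0[0, 1] * J0[1, 0]) ** 2 * CpE * CpI))
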