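"""Random connectivity and Euler integration of the rate models.

Connectivity is Bernoulli(K/N): each of the N^2 ordered pairs is a synapse
independently with probability K/N, giving mean in-degree K.  With the
balanced-state scaling J = -J0/sqrt(K), I = sqrt(K) I0, the one-population
inhibitory rate model reads

    tau dh_i/dt = -h_i + sqrt(K) I0 - (J0/sqrt(K)) sum_j C_ij g(h_j)

and the two-population model keeps one filtered variable h^{ab} per synapse
type (a = postsynaptic population, b = presynaptic), with net input
h^b = h^{bE} - h^{bI} + sqrt(K) I0^b.

The integrators are fixed-step Euler (default dt = tau/20) with numba
kernels; identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .transfer import TransferFunction

__all__ = [
    "NetworkParams",
    "Connectivity",
    "RateTrajectory",
    "sample_connectivity",
    "simulate_rate_onepop",
    "simulate_rate_twopop",
    "OnePopRateDynamics",
    "TwoPopRateDynamics",
]

_POPS = ("E", "I")
_BLOCKS = ("EE", "EI", "IE", "II")


def _tf_code(tf: TransferFunction) -> tuple[int, float]:
    if tf.kind == "sigmoid_erf":
        return 0, 0.0
    if tf.kind in ("threshold_power", "threshold_linear"):
        return 1, tf.gamma
    return 2, tf.tau_m


@dataclass
class NetworkParams:
    """Parameters of a (one- or two-population) random balanced network.

    ``J0``/``I0``/``tau`` are scalars for one population; for two
    populations ``J0`` and ``tau`` are 2x2 arrays indexed [post, pre] with
    rows/columns ordered (E, I), and ``I0`` is the pair (I0^E, I0^I).
    All couplings are stored as magnitudes; inhibition's sign is applied in
    the update rule.
    """

    N: int
    K: int
    J0: float | np.ndarray
    I0: float | tuple
    tau: float | np.ndarray
    tf: TransferFunction
    seed: int = 0

    def __post_init__(self):
        if self.K > self.N:
            raise ValueError(f"K={self.K} exceeds N={self.N}")
        if self.K > self.N / 4:
            warnings.warn(f"K={self.K} is not small compared to N={self.N}; "
                          "the sparse mean-field limit assumes K << N")
        if np.any(np.asarray(self.tau) <= 0):
            raise ValueError("all time constants must be positive")

    @property
    def two_pop(self) -> bool:
        return np.ndim(self.J0) == 2


@dataclass
class Connectivity:
    """Sparse binary adjacency; one CSR block per (post, pre) pair.

    For a single population the only block is ``matrix``.
    """

    blocks: dict = field(default_factory=dict)

    @property
    def matrix(self):
        return self.blocks["II"] if "II" in self.blocks and len(self.blocks) == 1 \
            else self.blocks.get("single")

    def mean_in_degree(self, key: str = None):
        m = self.blocks[key] if key else self.matrix
        return m.getnnz() / m.shape[0]


def _bernoulli_csr(N: int, K: int, rng) -> sp.csr_matrix:
    p = K / N
    if p > 1:
        raise ValueError("K > N")
    counts = rng.binomial(N, p, size=N)
    indptr = np.zeros(N + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int32)
    for i in range(N):
        indices[indptr[i]:indptr[i + 1]] = np.sort(
            rng.choice(N, size=counts[i], replace=False)).astype(np.int32)
    data = np.ones(len(indices), dtype=np.float64)
    return sp.csr_matrix((data, indices, indptr), shape=(N, N))


def sample_connectivity(N: int, K: int, seed: int = 0,
                        two_pop: bool = False) -> Connectivity:
    """Draw Bernoulli(K/N) adjacency; rows = postsynaptic neurons.

    With ``two_pop`` four independent blocks (EE, EI, IE, II) are drawn from
    disjoint RNG streams derived from ``seed``.
    """
    if K < 0 or K > N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not two_pop:
        rng = np.random.default_rng(seed)
        return Connectivity({"single": _bernoulli_csr(N, K, rng)})
    blocks = {}
    for b, key in enumerate(_BLOCKS):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        blocks[key] = _bernoulli_csr(N, K, rng)
    return Connectivity(blocks)


@dataclass
class RateTrajectory:
    """Recorded (sub-sampled) trajectory of net synaptic inputs.

    ``h`` is (neurons_recorded, samples) for one population, or a dict of
    such arrays keyed by population for the two-population net inputs.
    """

    times: np.ndarray
    h: np.ndarray | dict
    dt: float
    stride: int
    final_state: np.ndarray | dict | None = None


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=False)
def _g_vec(code, par, x, out):
    for i in range(x.size):
        xi = x[i]
        if code == 0:
            # phi(x) = ndtr(x) via erf
            out[i] = 0.5 * (1.0 + math.erf(xi / 1.4142135623730951))
        elif code == 1:
            if xi <= 0.0:
                out[i] = 0.0
            elif par == 1.0:
                out[i] = xi
            else:
                out[i] = xi ** par
        else:
            if xi <= 1.0:
                out[i] = 0.0
            else:
                out[i] = -1.0 / (par * np.log(1.0 - 1.0 / xi))
    return out


@njit(cache=True)
def _csr_gather(indptr, indices, v, out):
    for i in range(out.size):
        acc = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            acc += v[indices[k]]
        out[i] = acc
    return out


@njit(cache=True)
def _onepop_steps(h, indptr, indices, n_steps, dt_tau, I_ext, Jeff,
                  code, par, rec, stride, rec_offset, n_rec):
    """Euler steps; records h[:n_rec] every ``stride`` steps into ``rec``
    starting at global step index ``rec_offset`` (-1 disables recording).
    Returns the number of samples written."""
    N = h.size
    g = np.empty(N)
    u = np.empty(N)
    wrote = 0
    for s in range(n_steps):
        _g_vec(code, par, h, g)
        _csr_gather(indptr, indices, g, u)
        for i in range(N):
            h[i] += dt_tau * (-h[i] + I_ext - Jeff * u[i])
        # divergence propagates through the dense coupling within a few
        # steps, so probing one component periodically suffices
        if s % 64 == 0 and not np.isfinite(h[0]):
            return -(s + 1)
        if rec_offset >= 0 and (s + rec_offset + 1) % stride == 0:
            idx = (s + rec_offset + 1) // stride - 1
            if 0 <= idx < rec.shape[1]:
                for i in range(n_rec):
                    rec[i, idx] = h[i]
                wrote += 1
    return wrote


@njit(cache=True)
def _twopop_steps(hEE, hEI, hIE, hII, iptrEE, idxEE, iptrEI, idxEI,
                  iptrIE, idxIE, iptrII, idxII, n_steps, dt, tau, Jeff,
                  IE_ext, II_ext, code, par, recE, recI, stride,
                  rec_offset, n_rec):
    """Euler steps of the four synaptic-input blocks (tau, Jeff are 2x2,
    [post, pre], order (E, I)).  Records net inputs of the first ``n_rec``
    neurons of each population."""
    N = hEE.size
    gE = np.empty(N)
    gI = np.empty(N)
    u = np.empty(N)
    netE = np.empty(N)
    netI = np.empty(N)
    for s in range(n_steps):
        for i in range(N):
            netE[i] = hEE[i] - hEI[i] + IE_ext
            netI[i] = hIE[i] - hII[i] + II_ext
        _g_vec(code, par, netE, gE)
        _g_vec(code, par, netI, gI)
        if Jeff[0, 0] != 0.0:
            _csr_gather(iptrEE, idxEE, gE, u)
            for i in range(N):
                hEE[i] += dt / tau[0, 0] * (-hEE[i] + Jeff[0, 0] * u[i])
        else:
            for i in range(N):
                hEE[i] -= dt / tau[0, 0] * hEE[i]
        if Jeff[0, 1] != 0.0:
            _csr_gather(iptrEI, idxEI, gI, u)
            for i in range(N):
                hEI[i] += dt / tau[0, 1] * (-hEI[i] + Jeff[0, 1] * u[i])
        else:
            for i in range(N):
                hEI[i] -= dt / tau[0, 1] * hEI[i]
        if Jeff[1, 0] != 0.0:
            _csr_gather(iptrIE, idxIE, gE, u)
            for i in range(N):
                hIE[i] += dt / tau[1, 0] * (-hIE[i] + Jeff[1, 0] * u[i])
        else:
            for i in range(N):
                hIE[i] -= dt / tau[1, 0] * hIE[i]
        if Jeff[1, 1] != 0.0:
            _csr_gather(iptrII, idxII, gI, u)
            for i in range(N):
                hII[i] += dt / tau[1, 1] * (-hII[i] + Jeff[1, 1] * u[i])
        else:
            for i in range(N):
                hII[i] -= dt / tau[1, 1] * hII[i]
        if s % 64 == 0 and not (np.isfinite(hEI[0]) and np.isfinite(hIE[0])
                                and np.isfinite(hII[0]) and np.isfinite(hEE[0])):
            return -(s + 1)
        if rec_offset >= 0 and (s + rec_offset + 1) % stride == 0:
            idx = (s + rec_offset + 1) // stride - 1
            if 0 <= idx < recE.shape[1]:
                for i in range(n_rec):
                    recE[i, idx] = hEE[i] - hEI[i] + IE_ext
                    recI[i, idx] = hIE[i] - hII[i] + II_ext
    return 0


@njit(cache=True)
def _csr_gather2(indptr, indices, v1, v2, out1, out2):
    # one pass over the (large, memory-bound) index stream serves both
    # trajectory copies of a Lyapunov pair
    for i in range(out1.size):
        a = 0.0
        b = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            a += v1[j]
            b += v2[j]
        out1[i] = a
        out2[i] = b
    return out1


@njit(cache=True)
def _twopop_steps_pair(X, Y, iptrEE, idxEE, iptrEI, idxEI,
                       iptrIE, idxIE, iptrII, idxII, n_steps, dt, tau, Jeff,
                       IE_ext, II_ext, code, par):
    """Advance two state copies of the two-population model in lockstep.
    X, Y are (4, N) arrays with rows (hEE, hEI, hIE, hII)."""
    N = X.shape[1]
    g1 = np.empty((2, N))
    g2 = np.empty((2, N))
    u1 = np.empty(N)
    u2 = np.empty(N)
    net = np.empty(N)
    iptrs = (iptrEE, iptrEI, iptrIE, iptrII)
    idxs = (idxEE, idxEI, idxIE, idxII)
    for s in range(n_steps):
        for c in range(2):
            S = X if c == 0 else Y
            G = g1 if c == 0 else g2
            for i in range(N):
                net[i] = S[0, i] - S[1, i] + IE_ext
            _g_vec(code, par, net, G[0])
            for i in range(N):
                net[i] = S[2, i] - S[3, i] + II_ext
            _g_vec(code, par, net, G[1])
        for blk in range(4):
            a, b = blk // 2, blk % 2
            f = dt / tau[a, b]
            if Jeff[a, b] == 0.0:
                for i in range(N):
                    X[blk, i] -= f * X[blk, i]
                    Y[blk, i] -= f * Y[blk, i]
                continue
            _csr_gather2(iptrs[blk], idxs[blk], g1[b], g2[b], u1, u2)
            J = Jeff[a, b]
            for i in range(N):
                X[blk, i] += f * (-X[blk, i] + J * u1[i])
                Y[blk, i] += f * (-Y[blk, i] + J * u2[i])
        if s % 64 == 0 and not (np.isfinite(X[1, 0]) and np.isfinite(Y[1, 0])):
            return -(s + 1)
    return 0


# ---------------------------------------------------------------------------
# high-level simulators
# ---------------------------------------------------------------------------


def _default_h0_onepop(params: NetworkParams) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 977]))
    return rng.normal(0.0, 1.0, params.N)


def simulate_rate_onepop(params: NetworkParams, C: Connectivity,
                         h0: np.ndarray | None = None, T: float = 100.0,
                         dt: float | None = None, record_start: float = 0.0,
                         record_stride: int | None = None,
                         n_record: int | None = None) -> RateTrajectory:
    """Euler integration of the one-population inhibitory rate model.

    Times are in units of the synaptic time constant unless ``params.tau``
    says otherwise.  Recording starts at ``record_start`` with the given
    stride (default tau/5).
    """
    tau = float(params.tau)
    if dt is None:
        dt = tau / 20.0
    if dt > tau / 20.0 + 1e-12:
        warnings.warn(f"dt={dt} coarser than tau/20; Euler accuracy suffers")
    if record_stride is None:
        record_stride = max(1, int(round(tau / 5.0 / dt)))
    if n_record is None:
        n_record = min(params.N, 1000)
    h = (np.array(h0, dtype=float, copy=True) if h0 is not None
         else _default_h0_onepop(params))
    if h.size != params.N:
        raise ValueError("h0 has wrong length")
    M = C.matrix
    code, par = _tf_code(params.tf)
    n_steps = int(round(T / dt))
    start_step = int(round(record_start / dt))
    n_samp = max((n_steps - start_step) // record_stride, 0)
    rec = np.empty((n_record, n_samp))
    Ieff = np.sqrt(params.K) * float(params.I0)
    Jeff = float(params.J0) / np.sqrt(params.K)
    if start_step > 0:
        ret = _onepop_steps(h, M.indptr, M.indices, start_step, dt / tau,
                            Ieff, Jeff, code, par, rec, record_stride, -1, 0)
        if ret < 0:
            raise FloatingPointError(f"non-finite state at step {-ret}")
    ret = _onepop_steps(h, M.indptr, M.indices, n_steps - start_step, dt / tau,
                        Ieff, Jeff, code, par, rec, record_stride, 0, n_record)
    if ret < 0:
        raise FloatingPointError(
            f"non-finite state at step {start_step - ret}")
    times = record_start + (np.arange(n_samp) + 1) * record_stride * dt
    return RateTrajectory(times, rec, dt, record_stride, final_state=h)


def simulate_rate_twopop(params: NetworkParams, C: Connectivity,
                         h0: dict | None = None, T: float = 100.0,
                         dt: float | None = None, record_start: float = 0.0,
                         record_stride: int | None = None,
                         n_record: int | None = None) -> RateTrajectory:
    """Euler integration of the two-population rate model.

    Records the *net* inputs h^E, h^I of the first ``n_record`` neurons per
    population (the quantities whose PAC the theory predicts).
    """
    J0 = np.asarray(params.J0, dtype=float)
    tau = np.broadcast_to(np.asarray(params.tau, dtype=float), (2, 2)).copy()
    if dt is None:
        dt = tau.min() / 20.0
    if record_stride is None:
        record_stride = max(1, int(round(tau.min() / 5.0 / dt)))
    if n_record is None:
        n_record = min(params.N, 1000)
    N = params.N
    if h0 is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 978]))
        h0 = {b: np.abs(rng.normal(0.0, 1.0, N)) for b in _BLOCKS}
    state = {b: np.array(h0[b], dtype=float, copy=True) for b in _BLOCKS}
    code, par = _tf_code(params.tf)
    n_steps = int(round(T / dt))
    start_step = int(round(record_start / dt))
    n_samp = max((n_steps - start_step) // record_stride, 0)
    recE = np.empty((n_record, n_samp))
    recI = np.empty((n_record, n_samp))
    sK = np.sqrt(params.K)
    IEe, IIe = sK * params.I0[0], sK * params.I0[1]
    Jeff = J0 / sK
    blocks = [C.blocks[b] for b in _BLOCKS]
    args = []
    for b in blocks:
        args.extend([b.indptr, b.indices])
    ret = _twopop_steps(state["EE"], state["EI"], state["IE"], state["II"],
                        *args, start_step, dt, tau, Jeff, IEe, IIe, code, par,
                        recE, recI, record_stride, -1, 0)
    if ret < 0:
        raise FloatingPointError(f"non-finite state at step {-ret}")
    ret = _twopop_steps(state["EE"], state["EI"], state["IE"], state["II"],
                        *args, n_steps - start_step, dt, tau, Jeff, IEe, IIe,
                        code, par, recE, recI, record_stride, 0, n_record)
    if ret < 0:
        raise FloatingPointError(f"non-finite state at step {start_step - ret}")
    times = record_start + (np.arange(n_samp) + 1) * record_stride * dt
    return RateTrajectory(times, {"E": recE, "I": recI}, dt, record_stride,
                          final_state=state)


# ---------------------------------------------------------------------------
# stepper objects (for the Lyapunov procedure)
# ---------------------------------------------------------------------------


class OnePopRateDynamics:
    """Stepping handle over the one-population rate model (Euler flow)."""

    def __init__(self, params: NetworkParams, C: Connectivity,
                 h0: np.ndarray | None = None, dt: float | None = None):
        self.params = params
        self.C = C
        tau = float(params.tau)
        self.dt = tau / 20.0 if dt is None else dt
        self._dt_tau = self.dt / tau
        self.state = (np.array(h0, dtype=float, copy=True) if h0 is not None
                      else _default_h0_onepop(params))
        self._code, self._par = _tf_code(params.tf)
        self._Ieff = np.sqrt(params.K) * float(params.I0)
        self._Jeff = float(params.J0) / np.sqrt(params.K)
        self._rec = np.empty((0, 0))

    def advance(self, T: float):
        n = int(round(T / self.dt))
        M = self.C.matrix
        ret = _onepop_steps(self.state, M.indptr, M.indices, n, self._dt_tau,
                            self._Ieff, self._Jeff, self._code, self._par,
                            self._rec, 1, -1, 0)
        if ret < 0:
            raise FloatingPointError(f"non-finite state at step {-ret}")

    def copy(self) -> "OnePopRateDynamics":
        return OnePopRateDynamics(self.params, self.C, h0=self.state,
                                  dt=self.dt)


class TwoPopRateDynamics:
    """Stepping handle over the two-population rate model; the flat ``state``
    concatenates the four synaptic-input blocks (EE, EI, IE, II)."""

    def __init__(self, params: NetworkParams, C: Connectivity,
                 state: np.ndarray | None = None, dt: float | None = None):
        self.params = params
        self.C = C
        self.tau = np.broadcast_to(
            np.asarray(params.tau, dtype=float), (2, 2)).copy()
        self.dt = self.tau.min() / 20.0 if dt is None else dt
        N = params.N
        if state is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([params.seed, 978]))
            state = np.abs(rng.normal(0.0, 1.0, 4 * N))
        self.state = np.array(state, dtype=float, copy=True)
        self._code, self._par = _tf_code(params.tf)
        sK = np.sqrt(params.K)
        self._IEe, self._IIe = sK * params.I0[0], sK * params.I0[1]
        self._Jeff = np.asarray(params.J0, dtype=float) / sK
        self._rec = np.empty((0, 0))

    def advance(self, T: float):
        n = int(round(T / self.dt))
        N = self.params.N
        views = [self.state[i * N:(i + 1) * N] for i in range(4)]
        args = []
        for b in _BLOCKS:
            m = self.C.blocks[b]
            args.extend([m.indptr, m.indices])
        ret = _twopop_steps(*views, *args, n, self.dt, self.tau, self._Jeff,
                            self._IEe, self._IIe, self._code, self._par,
                            self._rec, self._rec, 1, -1, 0)
        if ret < 0:
            raise FloatingPointError(f"non-finite state at step {-ret}")

    def advance_pair(self, other: "TwoPopRateDynamics", T: float):
        """Advance this copy and ``other`` in lockstep (shared index stream;
        about twice as fast as two separate advances)."""
        n = int(round(T / self.dt))
        N = self.params.N
        args = []
        for b in _BLOCKS:
            m = self.C.blocks[b]
            args.extend([m.indptr, m.indices])
        ret = _twopop_steps_pair(self.state.reshape(4, N),
                                 other.state.reshape(4, N), *args, n,
                                 self.dt, self.tau, self._Jeff,
                                 self._IEe, self._IIe, self._code, self._par)
        if ret < 0:
            raise FloatingPointError(f"non-finite state at step {-ret}")

    def copy(self) -> "TwoPopRateDynamics":
        return TwoPopRateDynamics(self.params, self.C, state=self.state,
                                  dt=self.dt)
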