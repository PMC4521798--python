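# Models and methods

This note records the models implemented in `ratechaos`, the conventions
and numerical choices behind them, and what the package's tests do and do
not establish.

## Network models

**Connectivity and balanced scaling.** Every network is a directed random
graph in which each ordered pair is a synapse independently with
probability `K/N` (mean in-degree `K`, `1 << K <= N`). Couplings and
drives use the balanced-state scaling `J = J0/sqrt(K)` (inhibition entering
with a minus sign in the update rule) and `I = sqrt(K) I0`. Under this
scaling the `O(sqrt(K))` excitatory drive and recurrent inhibition cancel
to leading order, leaving `O(1)` mean net inputs and fluctuations, and the
population rate is pinned near `I0/J0` with an `O(mu/sqrt(K))` correction.
Some published statements of these models omit the radicals typographically;
the square-root scaling is the only one under which the mean input stays
finite as `K` grows, and it is the convention used everywhere here.

**Rate models.** The state variables `h_i` are net synaptic inputs;
`tau dh_i/dt = -h_i + input` with the presynaptic rates `g(h_j)` entering
through the sparse adjacency. The two-population (E/I) model keeps one
filtered variable per synapse type `h^{ab}` (`a` postsynaptic, `b`
presynaptic), each with its own time constant `tau_ab`, and net inputs
`h^b = h^{bE} - h^{bI} + sqrt(K) I0^b`. Integration is fixed-step Euler
with `dt = tau_min/20` by default (halving `dt` is verified not to change
population statistics beyond realization noise). Initial conditions —
which neither theory nor published work pins down — are standard-normal
inputs (non-negative for the pathway variables); in the chaotic regime the
attractor statistics are initialization-independent, which the tests rely
on.

**Spiking models.** Leaky integrate-and-fire voltages (threshold 1, reset
0, no refractory period) with exponentially filtered synapses; the
non-leaky variant drops the leak term, making the effective f-I curve
threshold-linear. Time is measured in units of the membrane constant
`tau_m` (10 ms when converting to Hz); in these units the LIF transfer
function is `g(x) = -1/ln(1 - 1/x)` above threshold, and the time-average
of a synaptic trace that jumps by `1/tau_syn` per spike equals the firing
rate — the unique convention making the slow-synapse rate reduction exact,
with the balance rate `100 I0/J0` Hz. Voltages advance by a second-order
Runge-Kutta step; threshold crossings are located by linear interpolation
within the step, the spike registered there, and the remainder integrated
from reset. Per-spike increments are applied at step boundaries, an
`O(dt)` approximation at `dt = 0.1 ms`; a guard aborts if a voltage
overshoots far beyond threshold in one step (multiple crossings per step).
Only the aggregate incoming drive per neuron is stored (exact exponential
decay plus per-spike increments), so cost scales as `O(N)` per step plus
`O(K)` per spike.

## Mean-field theory

The self-consistent description replaces the recurrent input by a Gaussian
process with a quenched component (variance `sigma_inf = J0^2 q` across
neurons) and a temporal component; the central order parameter is the
population-averaged autocovariance (PAC) `sigma(tau)` of the net inputs.

All equations reduce to Gaussian moments of `g`, `g'` and the
antiderivative `G`:

- closed forms for the sigmoid (`erf` identities and Owen's T), and for
  the threshold power-law family via truncated-Gaussian moments (parabolic
  cylinder functions for non-integer exponents, with asymptotic guards for
  extreme arguments);
- Gauss-Hermite quadrature (201 nodes) for smooth integrands, and
  panelled Gauss-Legendre split at the threshold kink when the smoothing
  variance is small relative to `sigma0` (where Gauss-Hermite converges
  slowly); the LIF curve's moments use adaptive quadrature and its
  antiderivative a cached cumulative-quadrature spline;
- divergent moments (`int Dz g'^2` for LIF, and power laws with
  `gamma <= 1/2`) raise an explicit signal: there the theory predicts an
  unstable fixed point at any coupling.

Closed forms agree with adaptive quadrature to `1e-8` on a grid of
`(mu, sigma)` (tested).

**Fixed point and criticality.** The fixed point `(mu, sigma)` is solved
by nested scalar root finding: `mu` from the rate equation at trial
`sigma` (strictly monotone, bisection-bracketed), then the variance
residual on a log grid (the residual need not be monotone for steep power
laws). The critical coupling solves `J0^2 int Dz g'(mu + sqrt(sigma) z)^2
= 1` jointly with the fixed point. For the threshold-linear curve
criticality forces `mu = 0`, hence `Jc = sqrt(2)` independent of drive and
of `K`. For power laws with `gamma > 1` at `I0 = 1` the fixed-point
equations lose their solution by a fold before the instability condition
is met (and have no solution at all in the strict balance limit), so
`critical_coupling` reports this instead of a number; the non-monotone
`Jc(gamma)` on `gamma in (1/2, 1]` is reproduced at `K = 400`.

**Chaotic state.** `sigma(tau)` obeys Newtonian motion in a potential
`V(sigma; sigma0)` with conserved energy. The admissible solution starts
at rest at `sigma0` and creeps into the interior maximum `sigma_inf` of
`V` at equal potential height. The solver exploits this: for trial
`sigma0` it locates the interior maximum of `V` (sign changes of `V'` on a
grid dense near `sigma0`) and drives the height mismatch
`V(sigma_inf) - V(sigma0)` to zero by bisection — near onset the root
lives in a window of relative width `~1e-4` below the fixed-point
variance, which the adaptive bracketing resolves. The PAC curve then
integrates the second-order ODE (RK45, rtol `1e-10`) with termination
events at a `1e-4`-of-amplitude approach to the plateau, at overshoot, or
at velocity reversal; the event horizon is set from the curvature of `V`
at the plateau. Energy drift along the integrated curve stays below
`1e-6` relative (tested).

**Near-onset scaling.** Solving at `delta = J0 - Jc` between 0.5% and 10%
of `Jc` and fitting log-log slopes gives the amplitude exponent
(`alpha = 1` sigmoid, `alpha = 2` threshold-linear) and the decorrelation
exponent (`beta = -1/2` both); the threshold-linear scaling function
`(sigma - sigma_inf)/delta^2` against `tau sqrt(delta)` is fitted by
`A/cosh(x/x_dec)`, with `A` and `x_dec` computed, not assumed.

**Two populations.** Four unknowns `(mu^E, mu^I, sigma^E, sigma^I)`; in
the strict balance limit the rates are fixed linearly by the drives, and
the excitatory population falls silent when `J0^II < I0^I J0^EI / I0^E`
(the package solves the general root; for the standard parameter set the
boundary is 0.8). Finite `K` keeps the `mu/sqrt(K)` terms; a damped
Picard sweep backs up Newton when the initial guess is poor. Chaos onset
is the scalar condition combining the `g'^2` moments of both populations;
it is reproduced independently by the curvature of the
separation-of-time-scales potential (slaving the fast pathways), a
cross-module identity the tests verify. The general four-PAC second-order
system is exposed as a right-hand side for numerical exploration; it has
no potential structure and no closed solution.

## Chaos metrics

The PAC estimator follows the per-lag-pair-count formula (divisor
`N_t - |k|`), computed by FFT over a recorded subset of neurons (default
1000) at stride `tau/5`. Decaying PACs are fitted to `A/cosh(tau/t_d)`,
`A/cosh^2`, or offset variants by least squares, initialized from the
half-width and excluding lags below 2% of the amplitude (tail noise).

The maximum Lyapunov exponent uses Benettin resets: after a transient
(default `200 tau`), a twin trajectory displaced by `epsilon = 1e-6` (l2)
is renormalized whenever the separation reaches `D_max = 1e-3` or after
`T_max = 5 tau`, and `Lambda = sum ln(D/epsilon) / sum T` over 100
segments, averaged over network realizations. The estimator is validated
against a linear flow (exact Euler-discretized exponent) and against the
sign change at the sigmoid network's critical coupling. Spiking networks
get no Lyapunov exponent — threshold crossings make the reset procedure
ill-posed there — and chaoticity is argued through the quantitative match
of their fluctuation statistics with the rate model.

The fraction-of-unstable-networks scan classifies a realization as
unstable when the population-averaged temporal variance of the inputs
exceeds `1e-9` after a `256 tau` transient, and fits the fraction against
`J0` with a logistic.

## Stability spectra

The linearization about a fixed point is the sparse matrix
`M_ij = -(J0/sqrt(K)) C_ij g'(h0_j)` with instability at largest real
eigenvalue 1; `h0` is sampled from the fixed-point Gaussian. The
conjectured bulk radius `J0 sqrt(int Dz g'^2)` equals 1 exactly at the
critical coupling (an algebraic identity, tested to `1e-8`) and matches
ARPACK extreme eigenvalues at `N = 10^4`, `K = 400` within 5% across the
transition for sigmoid and threshold-linear curves. The isolated negative
outlier scales like `sqrt(K)`. Bulk *uniformity* of the eigenvalue disk
is only assessed qualitatively: at densely diagonalizable sizes
(`N ~ 2000`) the many near-zero columns (`g'` small deep below threshold)
leave visible radial structure, and the flat `N_eig/R` histogram seen at
`N = 10^4` is not yet reached, so the tests check histogram consistency
rather than flatness.

## Problem sizes and known limitations

- Published reference values for these models come from simulations with
  up to `N = 256,000` neurons and `163.84 s` of recording averaged over
  10 realizations. The package's standard runs are `N = 10^4, K = 800`,
  70 s equivalent for the one-population spiking network, `N = 4000` per
  population, `K = 400` for two-population rate runs, and
  `N = 4000..16000` for the finite-size convergence check — sizes chosen
  so the whole battery completes in tens of minutes on one core.
  Finite-size deviations from the mean-field curves shrink monotonically
  with `N` (tested at two sizes) but are visible at these scales.
- The two-population Lyapunov product `Lambda * tau_II` in the II-driven
  regime comes out near 0.2–0.4 at these sizes, well below the value
  (~1.7) reported from `N = 16000`-per-population simulations. The
  estimate is robust here to the integration step, to the perturbation
  window, and to the reset schedule, and grows mildly with `N` and `K`;
  for LIF-type transfer functions the `g'^2` moment diverges and
  stability quantities are known to converge extremely slowly with
  network size, so this number should be treated as strongly
  size-dependent. The package reports what it measures.
- Power-law transfer functions with `gamma > 1` have no mean-field fixed
  point at `I0 = 1` (fold before instability; see above), so no critical
  coupling is reported there.
- Oscillatory PAC solutions (energy above the admissible separatrix) are
  detected and rejected as inadmissible, not analyzed; Hopf/synchrony
  instabilities of the two-population model are out of scope.
- Synthetic data throughout are generated by the package's own network
  simulators: Bernoulli connectivity, homogeneous constant drive, no
  synaptic delays, no refractoriness, no conductance effects. Passing
  tests therefore establish the internal consistency of theory and
  simulation under these assumptions, not the behavior of cortical
  tissue.
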