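# ratechaos

Rate chaos in balanced spiking neuronal networks: simulators, dynamical
mean-field theory (DMFT) solvers, chaos metrics and sparse stability
spectra.

Cortical circuits operate in a *balanced* regime in which strong excitatory
and inhibitory inputs cancel to leading order. When some synapses are slow
compared to the membrane time constant, the network dynamics reduce to a
rate model for the synaptic inputs,

```
tau_syn dh_i/dt = -h_i + sqrt(K) I0 - (J0/sqrt(K)) sum_j C_ij g(h_j),
```

with `C_ij ~ Bernoulli(K/N)` sparse random connectivity and `g` the
single-neuron f–I curve (sigmoid, threshold power law `x^gamma H(x)`, or
the leaky integrate-and-fire curve `-1/(tau_m ln(1 - 1/x))`). Above a
critical coupling `J_c` these networks develop *asynchronous rate chaos*:
firing rates fluctuate chaotically on the synaptic time scale while the
population stays asynchronous. This package is a toolchain for studying
that transition quantitatively:

- **`ratechaos.transfer`** — transfer functions and the Gaussian-moment
  calculus (closed forms + quadrature) every mean-field equation is built
  from.
- **`ratechaos.network`** — connectivity sampling and numba-accelerated
  Euler integration of the one- and two-population rate models.
- **`ratechaos.spiking`** — event-resolved LIF/NLIF network simulation
  (RK2 voltage steps, interpolated spike times, exponential synapses).
- **`ratechaos.dmft`** — self-consistent theory: fixed points, critical
  couplings, the potential/energy machinery for the population-averaged
  autocovariance (PAC) `sigma(tau)`, chaotic solutions, rate
  distributions, near-onset scaling, and the two-population balance and
  chaos-onset conditions.
- **`ratechaos.metrics`** — PAC estimation, cosh-family fits, the maximum
  Lyapunov exponent (Benettin resets) and fraction-of-stable-networks
  scans.
- **`ratechaos.spectra`** — sparse stability matrices and the closed-form
  prediction for their largest real eigenvalue.

## Worked example

Solve the mean-field theory of the inhibitory sigmoid network above the
transition and compare with a direct network simulation:

```python
import numpy as np
from ratechaos import transfer as tr
from ratechaos.dmft import onepop as dmft
from ratechaos.network import NetworkParams, sample_connectivity, simulate_rate_onepop
from ratechaos.metrics import pac_estimate, fit_pac, PACCurve

sg = tr.sigmoid_erf()
print(dmft.critical_coupling(sg, I0=1.0))       # 4.995451723968...

sol = dmft.solve_chaotic(sg, J0=15.0, I0=1.0)   # K -> inf balance mode
print(sol.mu, sol.sigma0, sol.sigma_inf)
# -4.506575... 8.013267... 2.159849...

fit = fit_pac(PACCurve(sol.tau_grid, sol.sigma_of_tau - sol.sigma_inf,
                       source="dmft"), family="cosh2")
print(fit.amplitude, fit.tau_dec)               # 5.7349..., 3.0368...

p = NetworkParams(N=4000, K=400, J0=15.0, I0=1.0, tau=1.0, tf=sg, seed=9)
C = sample_connectivity(4000, 400, seed=9)
traj = simulate_rate_onepop(p, C, T=120.0, record_start=40.0)
print(np.mean(sg.g(traj.h)))                    # ~0.082, the finite-K balance rate
```

`critical_coupling` returns the coupling where the mean-field fixed point
loses stability (for the threshold-linear curve it is exactly `sqrt(2)`,
independent of the drive); `solve_chaotic` returns the self-consistent
chaotic state — the mean input `mu`, the equal-time input variance
`sigma0`, the quenched plateau `sigma_inf`, and the PAC curve, whose decay
time is the decorrelation time of the chaotic fluctuations. The simulated
mean rate sits on the balance prediction `I0/J0` up to the `O(1/sqrt(K))`
correction.

A thin command line mirrors the library:

```bash
ratechaos dmft critical --tf sigmoid --i0 1
ratechaos dmft solve --tf threshold_linear --j0 1.81 --i0 1 --out pac.csv
ratechaos dmft2 onset --jei 0.8 --ie 1 --ii 1 --jii 1.0 --k 400 --scan IE:0.2:30
ratechaos run --config experiment.yml --out artifacts/
ratechaos reproduce t1
```

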