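# netcov

Pairwise covariances in weakly correlated recurrent neuronal networks:
closed-form covariance functions of delay-coupled linear rate models, and
the linearization maps that carry binary, Hawkes and leaky
integrate-and-fire (LIF) network models onto them — each validated against
direct stochastic simulation of the original nonlinear dynamics.

The package is for computational neuroscientists who work with second-order
statistics of recurrent network activity: it answers *what covariance
structure a given connectivity produces*, and conversely provides the
analytic forms needed to reason about connectivity from measured
correlations, including the effects of synaptic conduction delays and
inhibition.

## The model

A network of linear rate units with exponential kernel
`h(s) = (1/τ) θ(s) e^(−s/τ)`, conduction delay `d`, weight matrix **w** and
white noise of power `ρ²` has the cross spectrum

    input noise  : C(ω) = (H_d(ω)⁻¹ − w)⁻¹ D (H_d(−ω)⁻¹ − wᵀ)⁻¹
    output noise : C(ω) = (1 − H_d(ω) w)⁻¹ D (1 − H_d(−ω) wᵀ)⁻¹

with `H_d(ω) = e^(−iωd)/(1 + iωτ)`.  Its poles — the collective modes — are

    z_k(L) = i/τ − (i/d) W_k( L (d/τ) e^(d/τ) ),

one per branch `k` of the Lambert-W function and per eigenvalue `L` of
**w**.  For the population-averaged E/I system
(`M = Kw[[1, −γg], [1, −γg]]`, eigenvalues `{0, L = Kw(1−γg)}`) the package
evaluates the inverse Fourier transform exactly by the residue theorem,
giving `c(t)` in closed form, split into a δ peak, a symmetric common-input
term and an "echo" term that vanishes for `|t| < d` and jumps at `|t| = d`.

The nonlinear models attach to this backbone through their working points:

| model  | linearization | effective weights | noise | class |
|--------|---------------|-------------------|-------|-------|
| binary | slope of gain at the working point, or Gaussian-averaged slope `⟨φ′⟩` | `β_eff J` | `ρ² = 2τ a(1−a)` | input |
| Hawkes | rectification probability | `P_{μ,σ}(r>0) · J` | `ρ² = λ₀` | output |
| LIF    | DC-susceptibility `∂r_i/∂r_j = αJ + βJ²` + fitted kernel `τ_eff` | `αJ + βJ²` | `ρ² = r` | output |

## A worked example

```
$ python examples/poles_and_oscillations.py
eigenvalue L = -1.72, tau = 10.0 ms, delay d = 3.0 ms
poles returned: 41 (branches |k| <= 20)
max characteristic-equation residual: 3.42e-14
stable: True
least-damped pole: z = -0.3634+0.2894j 1/ms
  -> collective oscillation at 57.8 Hz, damping time 3.5 ms
d = 0 reference: single pole 0.0000+0.2720j (pure decay, no ringing)
```

Delayed net inhibition (`L = −1.72`) turns the single relaxation pole of the
instantaneous system into an infinite family of damped oscillatory modes;
the least-damped one sets the ~58 Hz peak of the population power spectrum
and the ringing of the covariance function.

The other scripts in `examples/` walk through the remaining capabilities —
`reduced_covariance.py` (closed-form vs simulated covariance of the E/I
system, equal blocks below the delay, echo jump at `|t| = d`),
`binary_pipeline.py` (working point → Gaussian-averaged slope → mapped
theory vs binary simulation, delay-controlled oscillation),
`hawkes_pipeline.py` (self-consistent rectified rate), `lif_pipeline.py`
(stationary rate, susceptibility, effective kernel) and
`echo_decomposition.py` (analytic and auxiliary-population echo/common-input
split).

Typical entry points:

```python
import numpy as np
from netcov import (ExponentialKernel, NetworkSpec, NoisePlacement,
                    reduce_network, covariance_time_domain, simulate_lrm)

spec   = NetworkSpec(N_e=1000, gamma=0.25, p=0.1, w=0.0688, g=5.0)
net    = reduce_network(spec, rho2=1.0)          # 2x2 system, L = -1.72
kernel = ExponentialKernel(tau=10.0, d=3.0)
noise  = NoisePlacement("output", 1.0)

lags   = np.arange(-50, 50.001, 0.5)
theory = covariance_time_domain(net, kernel, noise, lags)   # exact c(t)
traj   = simulate_lrm(net, kernel, noise, T=1e5, seed=0)    # direct simulation
```

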