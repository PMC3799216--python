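"""LIF network: stationary rate, DC-susceptibility and effective kernel.

The stationary rate of the leaky integrate-and-fire neuron with exponential
synaptic currents follows the colored-noise rate formula; the
DC-susceptibility w_ij = alpha J_ij + beta J_ij^2 and an empirically fitted
exponential kernel map the network onto the output-noise OU system with
rho2 = r (delta-peak autocovariance of the spike trains).
"""

import numpy as np

from netcov import LIFParams, NetworkSpec, lif_linearize, stationary_rates
from netcov.lif import estimate_effective_tau, susceptibility

spec = NetworkSpec(N_e=400, gamma=0.25, p=0.5, w=0.032, g=6.0,
                   degree_mode="fixed_in")
params = LIFParams(ext_rate=19.2, ext_weight=0.1,
                   ext_rate_i=9.6, ext_weight_i=-0.1)
J = 0.032   # excitatory PSP amplitude, mV

state = stationary_rates(params, spec, J)
print(f"self-consistent rate r = {state.rate*1000:.2f} Hz")
print(f"input moments: mu = {state.mu:.2f} mV, sigma = {state.sigma:.2f} mV")

s = susceptibility(params, state)
print(f"susceptibility coefficients: alpha = {s.alpha:.4f} /mV, beta = {s.beta:.5f} /mV^2")
print(f"effective weights: w_e = {s.weight(J):.5f}, w_i = {s.weight(-spec.g*J):.5f}")

tau_eff = estimate_effective_tau(params, state, J_impulse=0.15, seed=1)
print(f"effective kernel time constant (impulse response fit): {tau_eff:.2f} ms"
      f" (membrane tau_m = {params.tau_m} ms)")

lin = lif_linearize(params, state, spec, J, tau_eff=tau_eff)
print(f"mapped output-noise model: L = {lin.reduced.L:+.3f}, rho2 = r ="
      f" {lin.noise.rho2*1000:.2f} Hz")
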