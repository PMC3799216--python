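"""Closed-form covariance of the population-averaged E/I network, checked
against a direct simulation of the delay-coupled OU system.

The 2x2 reduced system (excitatory/inhibitory population averages) admits an
exact residue-theorem solution for the covariance function.  With output-side
noise all four blocks coincide for |t| < d and the echo of a unit's own
fluctuation appears as a jump at |t| = d.
"""

import numpy as np

from netcov import (
    ExponentialKernel,
    NetworkSpec,
    NoisePlacement,
    covariance_time_domain,
    reduce_network,
    simulate_lrm,
)
from netcov.estimation import estimate_covariance

spec = NetworkSpec(N_e=1000, gamma=0.25, p=0.1, w=0.0688, g=5.0)
net = reduce_network(spec, rho2=1.0)
kernel = ExponentialKernel(tau=10.0, d=3.0)
noise = NoisePlacement("output", 1.0)
print(f"reduced eigenvalue L = {net.L:.3f} (stable, oscillatory)")

traj = simulate_lrm(net, kernel, noise, T=1e5, dt=0.05, seed=1)
est = estimate_covariance(traj, 0.05, 30.0)
theory = covariance_time_domain(net, kernel, noise, est.lags)

print(f"{'lag':>6} {'c_ee sim':>12} {'c_ee theory':>12} {'c_ei sim':>12} {'c_ei theory':>12}")
for lag in (0.5, 1.5, 2.5, 3.5, 5.0, 10.0, 20.0):
    k = int(np.argmin(np.abs(est.lags - lag)))
    print(f"{lag:6.1f} {est.blocks[k,0,0]:12.3e} {theory.blocks[k,0,0]:12.3e} "
          f"{est.blocks[k,0,1]:12.3e} {theory.blocks[k,0,1]:12.3e}")
print("note: for 0 < t < d = 3 ms the ee and ei entries coincide (causality:")
print("no network interaction has arrived yet); at t = d the ei entry jumps")
print("down as the inhibitory echo arrives. The delta peak D_bar sits in the")
print(f"zero-lag bin (weight diag {np.diag(theory.delta_weight)}).")
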