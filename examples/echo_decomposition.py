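"""Echo vs common-input decomposition of the network covariance.

The output-noise covariance splits into three parts: the delta peak of each
unit's own noise, the symmetric term from shared input, and the "echo" of a
unit's own fluctuation returning through the network - zero for |t| < d and
jumping at |t| = d.  The same split is measured empirically with auxiliary
read-only units that receive the full network input but project nowhere.
"""

import numpy as np

from netcov import ExponentialKernel, NoisePlacement, decompose_covariance
from netcov.estimation import empirical_decomposition
from netcov.network import ReducedNetwork

L, gamma, g = -1.72, 0.25, 5.0
Kw = L / (1 - gamma * g)
net = ReducedNetwork(M=Kw * np.array([[1, -gamma * g], [1, -gamma * g]]),
                     D_bar=np.diag([1 / 100, 1 / 25]), L=L, K=10)
kernel = ExponentialKernel(tau=10.0, d=3.0)
noise = NoisePlacement("output", 1.0)

t = np.arange(-20, 20.001, 0.5)
parts = decompose_covariance(net, kernel, noise, t)
k1, k5 = np.argmin(np.abs(t - 1.0)), np.argmin(np.abs(t - 5.0))
print("analytic split of c_ee (output noise):")
for name, p in parts.items():
    print(f"  {name:20s}  c(1 ms) = {p.blocks[k1,0,0]: .3e}   c(5 ms) = {p.blocks[k5,0,0]: .3e}")
print("  -> the echo term is exactly zero below the delay d = 3 ms")

dec = empirical_decomposition(net, kernel, noise, T=1e5, dt=0.1, seed=3,
                              max_lag=20.0)
ke = np.argmin(np.abs(dec["full"].lags - 5.0))
print("\nauxiliary-population measurement at t = 5 ms:")
print(f"  common (aux pairs)   = {dec['common_input_estimate'].blocks[ke,0,0]: .3e}"
      f"  (theory {parts['common_input_term'].blocks[k5,0,0]: .3e})")
print(f"  echo (full - common) = {dec['echo_estimate'].blocks[ke,0,0]: .3e}"
      f"  (theory {parts['echo_term'].blocks[k5,0,0]: .3e})")
print("conservation: common + echo = full estimate, exactly by construction")
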