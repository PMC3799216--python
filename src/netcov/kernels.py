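"""Response kernels of the linear rate dynamics.

The toolkit works with the exponential (low-pass) kernel throughout: a unit
whose rate relaxes with time constant ``tau`` after a perturbation, receiving
its recurrent input after an axonal/synaptic conduction delay ``d``.  With this
kernel the linear rate model is a set of delay-coupled Ornstein-Uhlenbeck
processes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ExponentialKernel"]


@dataclass(frozen=True)
class ExponentialKernel:
    """Exponential response kernel with conduction delay.

    Time domain (``s`` in ms)::

        h(s)   = (1/tau) * theta(s) * exp(-s/tau)      # unit integral
        h_d(s) = h(s - d)                              # delayed kernel

    Frequency domain (angular frequency ``omega`` in 1/ms)::

        H(omega)   = 1 / (1 + i*omega*tau)
        H_d(omega) = exp(-i*omega*d) * H(omega)

    Parameters
    ----------
    tau:
        Relaxation time constant in ms, > 0.
    d:
        Conduction delay in ms, >= 0.
    """

    tau: float
    d: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("kernel time constant tau must be positive")
        if self.d < 0:
            raise ValueError("delay d must be non-negative")

    def h(self, s, delayed: bool = True):
        """Time-domain kernel evaluated at lag ``s`` (ms)."""
        s = np.asarray(s, dtype=float)
        shift = self.d if delayed else 0.0
        out = np.where(s > shift, np.exp(-(s - shift) / self.tau) / self.tau, 0.0)
        return out

    def transfer(self, omega, delayed: bool = True):
        """Transfer function ``H(omega)`` or ``H_d(omega)``.

        Accepts real or complex ``omega`` (analytic continuation).  At the
        kernel pole ``omega = i/tau`` the result is infinite.
        """
        omega = np.asarray(omega, dtype=complex)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 1.0 / (1.0 + 1j * omega * self.tau)
        if delayed and self.d != 0.0:
            out = out * np.exp(-1j * omega * self.d)
        return out

    def transfer_inverse(self, omega):
        """Inverse delayed transfer ``H_d(omega)^-1 = (1 + i*omega*tau) e^{i*omega*d}``.

        Entire function of ``omega``; returns 0 at the kernel pole ``i/tau``.
        """
        omega = np.asarray(omega, dtype=complex)
        return (1.0 + 1j * omega * self.tau) * np.exp(1j * omega * self.d)

    def with_delay(self, d: float) -> "ExponentialKernel":
        return ExponentialKernel(self.tau, d)
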