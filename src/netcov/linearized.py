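"""Container produced by each model's linearization step.

The binary, Hawkes and LIF mappings all end in the same object: an effective
weight matrix (or reduced 2x2 system), a noise placement with power ``rho2``
and a response kernel.  The analytic engine consumes it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import ExponentialKernel
from .linear_theory import NoisePlacement
from .network import ReducedNetwork

__all__ = ["LinearizedModel"]


@dataclass
class LinearizedModel:
    """Effective linear rate model obtained from a nonlinear network model.

    ``weights`` is the full effective matrix (may be ``None`` if only the
    reduced system is of interest); ``reduced`` the population-averaged
    2x2 system carrying the matching noise matrix ``D_bar``.
    """

    noise: NoisePlacement
    kernel: ExponentialKernel
    weights: np.ndarray | None = None
    reduced: ReducedNetwork | None = None
    meta: dict = field(default_factory=dict)

    @property
    def rho2(self):
        return self.noise.rho2
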