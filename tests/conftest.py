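import numpy as np
import pytest

from netcov import ExponentialKernel, NoisePlacement
from netcov.network import ReducedNetwork


@pytest.fixture
def fig_kernel():
    """Reference delayed kernel: tau = 10 ms, d = 3 ms."""
    return ExponentialKernel(10.0, 3.0)


@pytest.fixture
def reduced_net():
    """Reference reduced E/I system with eigenvalue L = -1.72."""
    L, gamma, g = -1.72, 0.25, 5.0
    Kw = L / (1.0 - gamma * g)
    M = Kw * np.array([[1.0, -gamma * g], [1.0, -gamma * g]])
    D = np.diag([1.0 / 1000, 1.0 / 250])
    return ReducedNetwork(M=M, D_bar=D, L=L, K=100, N_e=1000, N_i=250)


@pytest.fixture
def input_noise():
    return NoisePlacement("input", 1.0)


@pytest.fixture
def output_noise():
    return NoisePlacement("output", 1.0)


def frac_within(est_blocks, th_blocks, se, mask=None):
    """Fraction of points with |sim - theory| <= 3 SE, and the max z."""
    if mask is None:
        mask = np.ones(est_blocks.shape[0], dtype=bool)
    z = np.abs(est_blocks[mask] - th_blocks[mask]) / se[mask]
    return float((z <= 3.0).mean()), float(z.max())
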