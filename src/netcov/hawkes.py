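"""Multivariate Hawkes processes with delays, inhibition and rectification.

Each neuron fires as an inhomogeneous Poisson process with intensity
``lambda_i = [r_i]_+`` where ``r = nu + h_d * (J s)`` is a base rate plus
delayed, exponentially filtered input from the network spike trains ``s``.
Without rectification (all rates positive) the covariance obeys the linear
convolution equation ``c = h_d * (J c) + D_r`` and maps exactly onto the
output-noise linear rate model with ``w = J`` and ``rho2`` equal to the mean
rate.  Rectification is handled by the Gaussian linearization: with
``mu = nu + lambda0 K J (1 - g gamma)`` and
``sigma = J sqrt(lambda0 / (2 tau) K (1 + g^2 gamma))`` (Campbell's theorem
for the exponential kernel), the stationary rate solves::

    lambda0 = sigma/sqrt(2 pi) exp(-mu^2 / 2 sigma^2) + mu P_{mu,sigma}(r > 0)

and the effective linearized connectivity is ``w = P_{mu,sigma}(r > 0) J``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sps
from scipy.special import erf

from .kernels import ExponentialKernel
from .linear_theory import NoisePlacement
from .linearized import LinearizedModel
from .network import ConnectivityMatrix, NetworkSpec, reduce_from_weights
from .trains import SpikeTrains

__all__ = [
    "HawkesParams",
    "SelfConsistentRate",
    "SpikeTrains",
    "simulate_hawkes",
    "selfconsistent_rate",
    "hawkes_linearize",
]


@dataclass
class HawkesParams:
    """Hawkes network: base rate ``nu`` (1/ms), weight matrix ``J``
    (dimensionless kernel weights), exponential kernel with delay, and the
    rectification flag (clip negative intensities at zero)."""

    nu: float
    J: np.ndarray
    kernel: ExponentialKernel
    rectify: bool = True

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("base rate nu must be >= 0")
        if isinstance(self.J, ConnectivityMatrix):
            self.J = self.J.weights
        if sps.issparse(self.J):
            self.J = self.J.toarray()
        self.J = np.asarray(self.J, dtype=float)


@dataclass
class SelfConsistentRate:
    """Solution of the rectified rate equation."""

    lambda0: float
    mu: float
    sigma: float
    p_above: float       # P_{mu,sigma}(r > 0)


def simulate_hawkes(params: HawkesParams, T: float, seed: int = 0,
                    guard_factor: float = 1e3) -> SpikeTrains:
    """Exact thinning (Ogata) simulation of the delayed Hawkes network.

    Synaptic traces are kept per neuron, split into the positive-weight part
    ``P`` and negative-weight part ``Mn`` (both decay with the kernel time
    constant).  Between events ``P`` only decays, so ``sum(nu + P)`` evaluated
    at the current time bounds the total intensity until the next delayed
    delivery; candidate events are thinned against the true intensity
    ``[nu + P + Mn]_+``.  Delivery of a spike is delayed by ``d`` through a
    FIFO queue (spike times are generated in order).
    """
    J = params.J
    N = J.shape[0]
    tau, d = params.kernel.tau, params.kernel.d
    nu = params.nu
    rng = np.random.default_rng(seed)

    # per-source split columns, scaled to trace jumps J/tau
    pos_targets = [np.flatnonzero(J[:, j] > 0) for j in range(N)]
    pos_w = [J[pos_targets[j], j] / tau for j in range(N)]
    neg_targets = [np.flatnonzero(J[:, j] < 0) for j in range(N)]
    neg_w = [J[neg_targets[j], j] / tau for j in range(N)]

    P = np.zeros(N)
    Mn = np.zeros(N)
    t_state = 0.0            # time to which the traces are decayed

    times, ids = [], []
    queue_t, queue_j = [], []    # pending deliveries (FIFO)
    q_head = 0
    t = 0.0
    lam_scale = max(nu, 1e-12)
    neg_evals = 0
    n_evals = 0

    def decay_to(t_new):
        nonlocal t_state
        if t_new > t_state:
            fac = math.exp(-(t_new - t_state) / tau)
            P[:] *= fac
            Mn[:] *= fac
            t_state = t_new

    while True:
        B = N * nu + P.sum()
        t_cand = t + rng.exponential(1.0 / B) if B > 0 else np.inf
        next_del = queue_t[q_head] if q_head < len(queue_t) else np.inf
        if next_del <= t_cand:
            if next_del >= T:
                break
            # deliver first, then redraw (the bound changes; exact by
            # memorylessness of the candidate process)
            decay_to(next_del)
            j = queue_j[q_head]
            P[pos_targets[j]] += pos_w[j]
            Mn[neg_targets[j]] += neg_w[j]
            q_head += 1
            t = next_del
            continue
        if t_cand >= T:
            break
        t = t_cand
        decay_to(t)
        r = nu + P + Mn
        lam = np.maximum(r, 0.0) if params.rectify else r
        if not params.rectify and np.any(r < 0):
            raise RuntimeError("negative intensity with rectify=False")
        neg_evals += int(np.count_nonzero(r < 0))
        n_evals += N
        S = lam.sum()
        if S > guard_factor * N * lam_scale:
            raise RuntimeError("supercritical: runaway intensity")
        u = rng.random() * B
        if u < S:
            i = int(np.searchsorted(np.cumsum(lam), u))
            times.append(t)
            ids.append(i)
            queue_t.append(t + d)
            queue_j.append(i)

    frac_neg = neg_evals / n_evals if n_evals else 0.0
    if frac_neg > 0.25:
        import warnings

        warnings.warn(
            f"intensity negative for ~{frac_neg:.0%} of neuron-time: "
            "the rectified linearization degrades in this regime", RuntimeWarning)
    return SpikeTrains(times=np.asarray(times), ids=np.asarray(ids, dtype=int),
                       duration=T, n_neurons=N,
                       meta={"rectified_fraction": frac_neg})


def _rate_rhs(lam, nu, c_mu, c_s2):
    mu = nu + c_mu * lam
    sigma = math.sqrt(max(c_s2 * lam, 0.0))
    if sigma == 0.0:
        return max(mu, 0.0), mu, sigma, 1.0 if mu > 0 else (0.5 if mu == 0 else 0.0)
    p_above = 0.5 - 0.5 * erf(-mu / (math.sqrt(2.0) * sigma))
    lam_new = sigma / math.sqrt(2.0 * math.pi) * math.exp(-mu**2 / (2 * sigma**2)) \
        + mu * p_above
    return lam_new, mu, sigma, p_above


def selfconsistent_rate(
    spec: NetworkSpec,
    J: float,
    nu: float,
    kernel: ExponentialKernel,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> SelfConsistentRate:
    """Stationary rate of the rectified Hawkes network.

    Fixed point of ``lambda0 = E[ [r]_+ ]`` under the Gaussian approximation
    of the input, with ``mu(lambda0) = nu + lambda0 K J (1 - g gamma)`` and
    ``sigma(lambda0)`` from Campbell's theorem for the exponential kernel.
    """
    K, gamma, g = spec.K, spec.gamma, spec.g
    tau = kernel.tau
    c_mu = K * J * (1.0 - g * gamma)
    c_s2 = J**2 * K * (1.0 + g**2 * gamma) / (2.0 * tau)

    lam = max(nu, 1e-6)
    for _ in range(max_iter):
        lam_new, mu, sigma, p_above = _rate_rhs(lam, nu, c_mu, c_s2)
        if abs(lam_new - lam) < tol:
            lam = lam_new
            break
        lam = 0.5 * lam + 0.5 * lam_new
    lam_new, mu, sigma, p_above = _rate_rhs(lam, nu, c_mu, c_s2)
    if abs(lam_new - lam) > 1e-10:
        raise RuntimeError("no stationary rate: self-consistency did not converge")
    if lam < 0:
        raise RuntimeError("no stationary rate: negative fixed point")
    return SelfConsistentRate(lambda0=lam, mu=mu, sigma=sigma, p_above=p_above)


def hawkes_linearize(
    spec: NetworkSpec,
    J: float,
    sc: SelfConsistentRate,
    kernel: ExponentialKernel,
) -> LinearizedModel:
    """Output-noise LRM equivalent of the rectified Hawkes network.

    Every weight is scaled by the probability ``P(r > 0)`` that a neuron is
    above threshold; the noise power equals the stationary rate,
    ``rho2 = lambda0`` (Poisson delta-autocovariance).
    """
    w_e = sc.p_above * J
    w_i = -sc.p_above * spec.g * J
    reduced = reduce_from_weights(spec.N_e, spec.gamma, spec.K, w_e, w_i, sc.lambda0)
    noise = NoisePlacement("output", sc.lambda0)
    return LinearizedModel(noise=noise, kernel=kernel, reduced=reduced,
                           meta={"lambda0": sc.lambda0, "p_above": sc.p_above})
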