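"""Asynchronous binary network model and its linear rate mapping.

Each of the ``N`` binary neurons is updated at independent exponentially
distributed intervals of mean ``tau``; at an update of neuron ``i`` the new
state is 1 with probability ``phi(J_i . n(t - d))`` where
``phi(x) = 1/2 + 1/2 tanh(beta x)`` and ``n(t - d)`` is the network state one
conduction delay in the past.

Linearized around the stationary working point (mean activity ``a``, input
mean ``mu = K J (1 - gamma g) a`` and variance
``sigma^2 = K J^2 (1 + gamma g^2) a (1 - a)``), the fluctuations obey the
input-noise linear rate model with effective weights ``w = beta_eff * J`` and
noise power ``rho2 = 2 tau a (1 - a)``.  The effective slope ``beta_eff`` is
either the slope of ``phi`` at the mean input or — more accurately — the
slope averaged over the Gaussian input distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sps

from .kernels import ExponentialKernel
from .linear_theory import NoisePlacement
from .linearized import LinearizedModel
from .network import ConnectivityMatrix, NetworkSpec, reduce_from_weights

__all__ = [
    "GainParams",
    "WorkingPoint",
    "BinaryTrajectory",
    "working_point",
    "effective_slope",
    "map_binary_to_lrm",
    "simulate_binary",
]

_GH_ORDER = 64
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(_GH_ORDER)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)   # probabilists' normalization


@dataclass(frozen=True)
class GainParams:
    """Sigmoidal gain ``phi(x) = 1/2 + 1/2 tanh(beta x)``.

    ``beta = inf`` is the hard-threshold limit ``phi = theta(x)``.
    """

    beta: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be positive (use np.inf for a hard threshold)")

    def phi(self, x):
        x = np.asarray(x, dtype=float)
        if np.isinf(self.beta):
            return np.where(x > 0, 1.0, np.where(x < 0, 0.0, 0.5))
        return 0.5 + 0.5 * np.tanh(self.beta * x)

    def phi_prime(self, x):
        x = np.asarray(x, dtype=float)
        if np.isinf(self.beta):
            raise ValueError("phi' is a delta function for beta = inf; "
                             "use the Gaussian-averaged slope")
        return 0.5 * self.beta / np.cosh(self.beta * x) ** 2


@dataclass
class WorkingPoint:
    """Stationary mean activity and input statistics of the binary network."""

    a: float
    mu: float
    sigma2: float

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)


def _gauss_avg(fn, mu, sigma):
    if sigma == 0.0:
        return float(fn(mu))
    x = mu + sigma * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * fn(x)))


def working_point(
    spec: NetworkSpec,
    J: float,
    gain: GainParams,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> WorkingPoint:
    """Self-consistent mean activity ``a = <phi>_{N(mu(a), sigma(a))}``.

    ``mu(a) = K J (1 - gamma g) a`` and
    ``sigma^2(a) = K J^2 (1 + gamma g^2) a (1 - a)``.  Solved by damped
    fixed-point iteration with a bisection fallback.
    """
    K, gamma, g = spec.K, spec.gamma, spec.g
    c_mu = K * J * (1.0 - gamma * g)
    c_s2 = K * J**2 * (1.0 + gamma * g**2)

    def rhs(a):
        mu = c_mu * a
        s2 = max(c_s2 * a * (1.0 - a), 0.0)
        return _gauss_avg(gain.phi, mu, math.sqrt(s2))

    a = 0.5
    for _ in range(max_iter):
        a_new = (1.0 - damping) * a + damping * rhs(a)
        if abs(a_new - a) < tol:
            a = a_new
            break
        a = a_new
    if abs(rhs(a) - a) > 1e-8:
        # bisection fallback on F(a) = rhs(a) - a
        lo, hi = 1e-12, 1.0 - 1e-12
        flo, fhi = rhs(lo) - lo, rhs(hi) - hi
        if flo * fhi > 0:
            raise RuntimeError(
                f"working point did not converge; no sign change of the "
                f"self-consistency residual on [{lo}, {hi}]")
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            fm = rhs(mid) - mid
            if flo * fm <= 0:
                hi = mid
            else:
                lo, flo = mid, fm
        a = 0.5 * (lo + hi)
    mu = c_mu * a
    s2 = max(c_s2 * a * (1.0 - a), 0.0)
    return WorkingPoint(a=a, mu=mu, sigma2=s2)


def effective_slope(gain: GainParams, wp: WorkingPoint, method: str = "gaussian_avg") -> float:
    """Effective linearization slope of the gain function.

    ``'at_mean'``: ``phi'(mu)``.  ``'gaussian_avg'``: ``<phi'>`` averaged over
    the Gaussian input distribution ``N(mu, sigma)`` (Gauss-Hermite
    quadrature); for ``beta = inf`` this is the Gaussian density at threshold,
    ``exp(-mu^2 / 2 sigma^2) / (sigma sqrt(2 pi))`` — finite even without
    local noise.
    """
    if method == "at_mean":
        return float(gain.phi_prime(wp.mu))
    if method != "gaussian_avg":
        raise ValueError("method must be 'at_mean' or 'gaussian_avg'")
    sigma = wp.sigma
    if np.isinf(gain.beta):
        if sigma == 0.0:
            raise ValueError("beta = inf with sigma = 0 has no finite slope")
        return math.exp(-wp.mu**2 / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))
    if sigma == 0.0:
        return float(gain.phi_prime(wp.mu))
    return _gauss_avg(gain.phi_prime, wp.mu, sigma)


def map_binary_to_lrm(
    spec: NetworkSpec,
    J: float,
    wp: WorkingPoint,
    beta_eff: float,
    tau: float,
    d: float,
) -> LinearizedModel:
    """Input-noise LRM equivalent of the linearized binary network.

    Effective weights ``w = beta_eff * J`` (elementwise, preserving the
    ``-g`` inhibition factor), noise power ``rho2 = 2 tau a (1 - a)``.
    """
    rho2 = 2.0 * tau * wp.a * (1.0 - wp.a)
    kernel = ExponentialKernel(tau, d)
    noise = NoisePlacement("input", rho2)
    w_e = beta_eff * J
    w_i = -beta_eff * spec.g * J
    reduced = reduce_from_weights(spec.N_e, spec.gamma, spec.K, w_e, w_i, rho2)
    return LinearizedModel(noise=noise, kernel=kernel, reduced=reduced,
                           meta={"a": wp.a, "beta_eff": beta_eff, "J": J})


@dataclass
class BinaryTrajectory:
    """Event list of state flips plus the initial state.

    ``flip_times`` / ``flip_ids`` / ``flip_states`` record every accepted
    state change; between flips the network state is constant.
    """

    initial_state: np.ndarray
    flip_times: np.ndarray
    flip_ids: np.ndarray
    flip_states: np.ndarray
    duration: float
    tau: float
    seed: int | None = None

    @property
    def N(self) -> int:
        return self.initial_state.size

    def binned(self, bin_width: float, indices=None, mean: bool = False) -> np.ndarray:
        """States sampled on a uniform grid (dimensionless activity).

        With ``mean=True`` returns the population-mean activity over
        ``indices``; otherwise one row per neuron.
        """
        nb = int(round(self.duration / bin_width))
        grid = np.arange(nb) * bin_width
        if indices is None:
            indices = np.arange(self.N)
        indices = np.asarray(indices)
        if mean:
            sel = np.isin(self.flip_ids, indices)
            t = self.flip_times[sel]
            delta = 2.0 * self.flip_states[sel] - 1.0
            base = float(self.initial_state[indices].sum())
            cum = np.concatenate([[base], base + np.cumsum(delta)])
            pos = np.searchsorted(t, grid, side="right")
            return cum[pos] / indices.size
        out = np.empty((indices.size, nb))
        for row, j in enumerate(indices):
            sel = self.flip_ids == j
            t = self.flip_times[sel]
            s = self.flip_states[sel].astype(float)
            cum = np.concatenate([[float(self.initial_state[j])], s])
            pos = np.searchsorted(t, grid, side="right")
            out[row] = cum[pos]
        return out

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_ms": self.flip_times, "neuron_id": self.flip_ids,
                      "state": self.flip_states}).to_csv(path, index=False)


def simulate_binary(
    J,
    gain: GainParams,
    tau: float,
    d: float,
    T: float,
    seed: int = 0,
    initial_state=None,
    chunk: int = 1 << 16,
) -> BinaryTrajectory:
    """Event-driven simulation of the asynchronous binary network.

    Exact asynchronous dynamics without time discretization: the pooled
    update process is Poisson with rate ``N/tau`` and each update hits a
    uniformly chosen neuron (equivalent to independent exponential clocks of
    mean ``tau``).  The delayed input ``J . n(t - d)`` is maintained
    incrementally from the flip history.  Reproducible by seed.
    """
    if isinstance(J, ConnectivityMatrix):
        J = J.weights
    if sps.issparse(J):
        J = J.toarray()
    J = np.asarray(J, dtype=float)
    N = J.shape[0]
    if d < 0:
        raise ValueError("delay must be >= 0")

    # per-source adjacency for incremental updates of the delayed drive
    targets = [np.flatnonzero(J[:, j]) for j in range(N)]
    weights = [J[targets[j], j] for j in range(N)]

    rng = np.random.default_rng(seed)
    if initial_state is None:
        state = (rng.random(N) < 0.5).astype(np.int8)
    else:
        state = np.asarray(initial_state, dtype=np.int8).copy()
    init_state = state.copy()

    n_delayed = state.copy()
    u = J @ n_delayed          # delayed input J . n(t - d), updated incrementally

    flip_t, flip_i, flip_s = [], [], []
    hist_ptr = 0               # next flip event to fold into the delayed state

    phi = gain.phi
    beta = gain.beta
    hard = np.isinf(beta)
    t = 0.0
    rate = N / tau
    while t < T:
        dts = rng.exponential(1.0 / rate, size=chunk)
        who = rng.integers(0, N, size=chunk)
        uni = rng.random(chunk)
        for e in range(chunk):
            t += dts[e]
            if t >= T:
                break
            # fold flips older than t - d into the delayed state and drive
            horizon = t - d
            while hist_ptr < len(flip_t) and flip_t[hist_ptr] <= horizon:
                j = flip_i[hist_ptr]
                ds = 2 * flip_s[hist_ptr] - 1
                n_delayed[j] += ds
                u[targets[j]] += ds * weights[j]
                hist_ptr += 1
            i = who[e]
            x = u[i]
            if hard:
                p = 1.0 if x > 0 else (0.0 if x < 0 else 0.5)
            else:
                p = 0.5 + 0.5 * math.tanh(beta * x)
            new = 1 if uni[e] < p else 0
            if new != state[i]:
                state[i] = new
                flip_t.append(t)
                flip_i.append(i)
                flip_s.append(new)

    return BinaryTrajectory(
        initial_state=init_state,
        flip_times=np.asarray(flip_t),
        flip_ids=np.asarray(flip_i, dtype=int),
        flip_states=np.asarray(flip_s, dtype=np.int8),
        duration=T,
        tau=tau,
        seed=seed,
    )
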