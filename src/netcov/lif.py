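"""Leaky integrate-and-fire networks with exponential synaptic currents.

Subthreshold dynamics of neuron ``i`` (membrane potential ``V``, synaptic
current ``I``, both in mV after absorbing the membrane resistance)::

    tau_m dV/dt = -V + I
    tau_s dI/dt = -I + tau_m * sum_j J_ij s_j(t - d)

with threshold ``V_theta``, reset ``V_r`` and refractory period ``tau_r``.
In the asynchronous irregular regime the summed input is approximated as
white noise with moments ``mu_i = tau_m sum_j J_ij r_j`` and
``sigma_i^2 = tau_m sum_j J_ij^2 r_j``; the stationary rate follows the
colored-noise (Fourcaud-Brunel) formula with the ``sqrt(tau_s/tau_m)``
boundary shift ``alpha/2 = |zeta(1/2)|/sqrt(2)``.  The DC-susceptibility
``w_ij = d r_i / d r_j = alpha J_ij + beta J_ij^2`` and the effective
exponential kernel map the network onto the output-noise linear rate model
with ``rho2 = r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.sparse as sps
from scipy.special import erfcx

from .kernels import ExponentialKernel
from .linear_theory import NoisePlacement
from .linearized import LinearizedModel
from .network import ConnectivityMatrix, NetworkSpec, reduce_from_weights
from .trains import SpikeTrains

__all__ = [
    "LIFParams",
    "StationaryState",
    "Susceptibility",
    "zeta_alpha",
    "simulate_lif",
    "stationary_rates",
    "lif_linearize",
    "estimate_effective_tau",
]


def zeta_alpha(n_terms: int = 40) -> float:
    """The boundary-shift constant ``alpha = sqrt(2) |zeta(1/2)|``.

    ``zeta(1/2)`` is evaluated through the alternating (Dirichlet eta) series
    with Cohen-Rodriguez Villegas-Zagier acceleration,
    ``zeta(s) = eta(s) / (1 - 2^(1-s))``; 40 terms give full double
    precision.
    """
    s = 0.5
    n = n_terms
    pw = (3.0 + math.sqrt(8.0)) ** n
    d = 0.5 * (pw + 1.0 / pw)
    b, c, eta = -1.0, -d, 0.0
    for k in range(n):
        c = b - c
        eta += c / (k + 1) ** s
        b *= (k + n) * (k - n) / ((k + 0.5) * (k + 1.0))
    eta /= d
    zeta_half = eta / (1.0 - 2.0 ** (1.0 - s))
    return math.sqrt(2.0) * abs(zeta_half)


_ALPHA = zeta_alpha()


@dataclass
class LIFParams:
    """Single-neuron and synapse parameters (times in ms, potentials in mV).

    ``ext_rate`` (1/ms) and ``ext_weight`` (mV) describe an independent
    Poisson drive per neuron, folded into the input moments via the diffusion
    approximation.  A second, typically inhibitory, source
    (``ext_rate_i``/``ext_weight_i``) allows a fluctuation-driven working
    point (large sigma at moderate mean) with small individual kicks.
    """

    tau_m: float = 20.0
    tau_s: float = 0.5
    tau_r: float = 2.0
    V_theta: float = 20.0
    V_r: float = 0.0
    d: float = 1.5
    ext_rate: float = 0.0
    ext_weight: float = 0.0
    ext_rate_i: float = 0.0
    ext_weight_i: float = 0.0

    def __post_init__(self) -> None:
        if self.V_theta <= self.V_r:
            raise ValueError("V_theta must exceed V_r")
        if min(self.tau_m, self.tau_s, self.tau_r) <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class StationaryState:
    """Self-consistent stationary rates and input moments."""

    rate: float            # 1/ms, homogeneous across the network
    mu: float              # mV
    sigma2: float          # mV^2
    zeta_alpha: float = _ALPHA

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)


@dataclass
class Susceptibility:
    """DC-susceptibility coefficients: ``w_ij = alpha J_ij + beta J_ij**2``."""

    alpha: float           # per mV
    beta: float            # per mV^2

    def weight(self, J):
        return self.alpha * np.asarray(J) + self.beta * np.asarray(J) ** 2


def _siegert_inverse(mu, sigma, p: LIFParams) -> float:
    """1/rate of the LIF neuron for white-noise input moments (ms)."""
    shift = 0.5 * _ALPHA * math.sqrt(p.tau_s / p.tau_m)
    y_th = (p.V_theta - mu) / sigma + shift
    y_r = (p.V_r - mu) / sigma + shift
    # f(y) = e^{y^2}(1 + erf(y)) = erfcx(-y), integrated adaptively
    val, _ = scipy.integrate.quad(lambda y: erfcx(-y), y_r, y_th, limit=200)
    return p.tau_r + p.tau_m * math.sqrt(math.pi) * val


def lif_rate(mu: float, sigma: float, p: LIFParams) -> float:
    """Stationary firing rate (1/ms) for given input moments."""
    if sigma <= 0:
        raise ValueError("sigma must be positive (fluctuation-driven formula)")
    return 1.0 / _siegert_inverse(mu, sigma, p)


def stationary_rates(
    params: LIFParams,
    spec: NetworkSpec,
    J: float,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> StationaryState:
    """Self-consistent homogeneous network rate.

    Recurrent moments ``mu_rec = tau_m K J (1 - gamma g) r`` and
    ``sigma2_rec = tau_m K J^2 (1 + gamma g^2) r`` plus the external-drive
    moments; solved by damped fixed-point iteration on the rate.
    """
    K, gamma, g = spec.K, spec.gamma, spec.g
    mu_ext = params.tau_m * (params.ext_weight * params.ext_rate
                             + params.ext_weight_i * params.ext_rate_i)
    s2_ext = params.tau_m * (params.ext_weight**2 * params.ext_rate
                             + params.ext_weight_i**2 * params.ext_rate_i)
    c_mu = params.tau_m * K * J * (1.0 - gamma * g)
    c_s2 = params.tau_m * K * J**2 * (1.0 + gamma * g**2)

    def moments(r):
        return mu_ext + c_mu * r, s2_ext + c_s2 * r

    r = 0.01
    for _ in range(max_iter):
        mu, s2 = moments(r)
        if s2 <= 0:
            raise RuntimeError("zero input variance: outside the fluctuation-driven regime")
        r_new = lif_rate(mu, math.sqrt(s2), params)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = 0.5 * r + 0.5 * r_new
    mu, s2 = moments(r)
    if abs(lif_rate(mu, math.sqrt(s2), params) - r) > 1e-8:
        raise RuntimeError(f"rate self-consistency did not converge; last iterate r={r}")
    if mu > params.V_theta:
        import warnings

        warnings.warn("mean input above threshold: mean-driven regime, "
                      "diffusion linearization may be inaccurate", RuntimeWarning)
    return StationaryState(rate=r, mu=mu, sigma2=s2)


def susceptibility(params: LIFParams, state: StationaryState) -> Susceptibility:
    """Analytic derivative of the stationary rate by an afferent's rate.

    ``alpha = sqrt(pi) (tau_m r)^2 (f(y_th) - f(y_r)) / sigma`` and
    ``beta = sqrt(pi) (tau_m r)^2 [f(y_th)(V_theta - mu) - f(y_r)(V_r - mu)]
    / (2 sigma^3)`` with ``f(y) = erfcx(-y)``.
    """
    p = params
    mu, sigma, r = state.mu, state.sigma, state.rate
    shift = 0.5 * _ALPHA * math.sqrt(p.tau_s / p.tau_m)
    y_th = (p.V_theta - mu) / sigma + shift
    y_r = (p.V_r - mu) / sigma + shift
    f_th, f_r = erfcx(-y_th), erfcx(-y_r)
    pref = math.sqrt(math.pi) * (p.tau_m * r) ** 2
    alpha = pref / sigma * (f_th - f_r)
    beta = pref / (2.0 * sigma**2) * (f_th * (p.V_theta - mu) / sigma
                                      - f_r * (p.V_r - mu) / sigma)
    return Susceptibility(alpha=alpha, beta=beta)


def lif_linearize(
    params: LIFParams,
    state: StationaryState,
    spec: NetworkSpec,
    J: float,
    tau_eff: float | None = None,
) -> LinearizedModel:
    """Output-noise LRM equivalent of the LIF network.

    Effective weights are the DC-susceptibilities ``alpha J + beta J^2`` per
    synapse; the noise power equals the rate (``rho2 = r``, spike-train
    delta-autocovariance); the kernel is exponential with the empirically
    determined effective time constant (default fallback: ``tau_m``).
    """
    susc = susceptibility(params, state)
    w_e = susc.weight(J)
    w_i = susc.weight(-spec.g * J)
    if tau_eff is None:
        tau_eff = params.tau_m
    kernel = ExponentialKernel(tau_eff, params.d)
    reduced = reduce_from_weights(spec.N_e, spec.gamma, spec.K, w_e, w_i, state.rate)
    noise = NoisePlacement("output", state.rate)
    return LinearizedModel(noise=noise, kernel=kernel, reduced=reduced,
                           meta={"rate": state.rate, "alpha": susc.alpha,
                                 "beta": susc.beta, "tau_eff": tau_eff})


def simulate_lif(
    params: LIFParams,
    J,
    T: float,
    dt: float = 0.05,
    seed: int = 0,
    warmup: float | None = None,
) -> SpikeTrains:
    """Grid-based LIF network simulation with exact subthreshold propagation.

    Between grid points the linear ``(V, I)`` system is integrated with its
    exact exponential propagator; spikes are detected at grid points (bias
    ``O(dt)``), delivered after the delay ``d`` (an integer multiple of
    ``dt``) as jumps ``tau_m J / tau_s`` of the synaptic current, and followed
    by clamping at ``V_r`` for ``tau_r``.  The external Poisson drive enters
    through the same synapse dynamics.
    """
    if isinstance(J, ConnectivityMatrix):
        J = J.weights
    if sps.issparse(J):
        J = J.toarray()
    J = np.asarray(J, dtype=float)
    N = J.shape[0]
    p = params
    if dt > min(p.tau_m, p.tau_s) / 10.0 + 1e-12:
        import warnings

        warnings.warn("dt coarser than min(tau_m, tau_s)/10", RuntimeWarning)
    D = p.d / dt
    if abs(D - round(D)) > 1e-9:
        raise ValueError("delay d must be an integer multiple of dt")
    D = max(int(round(D)), 1)
    if warmup is None:
        warmup = 10.0 * p.tau_m
    n_warm = int(round(warmup / dt))
    n_steps = n_warm + int(round(T / dt))
    ref_steps = max(int(round(p.tau_r / dt)), 1)

    e_m, e_s = math.exp(-dt / p.tau_m), math.exp(-dt / p.tau_s)
    eps = p.tau_s / (p.tau_s - p.tau_m)
    jump = p.tau_m / p.tau_s

    rng = np.random.default_rng(seed)
    V = rng.uniform(p.V_r, p.V_theta, size=N)
    I = np.zeros(N)
    refr = np.zeros(N, dtype=int)
    ring = np.zeros((D, N))            # pending current jumps
    times, ids = [], []
    lam_ext = p.ext_rate * dt
    lam_ext_i = p.ext_rate_i * dt

    for k in range(n_steps):
        idx = k % D
        arriving = ring[idx].copy()
        ring[idx] = 0.0
        if lam_ext > 0:
            arriving += jump * p.ext_weight * rng.poisson(lam_ext, size=N)
        if lam_ext_i > 0:
            arriving += jump * p.ext_weight_i * rng.poisson(lam_ext_i, size=N)
        # exact propagation over dt, then current jumps at the step boundary
        V = (V - eps * I) * e_m + eps * I * e_s
        I = I * e_s + arriving
        clamped = refr > 0
        V[clamped] = p.V_r
        refr[clamped] -= 1
        spk = np.flatnonzero((V >= p.V_theta) & ~clamped)
        if spk.size:
            V[spk] = p.V_r
            refr[spk] = ref_steps
            ring[idx] += jump * J[:, spk].sum(axis=1)      # read again at k + D
            if k >= n_warm:
                t_sp = (k - n_warm) * dt
                times.extend([t_sp] * spk.size)
                ids.extend(spk.tolist())

    return SpikeTrains(times=np.asarray(times), ids=np.asarray(ids, dtype=int),
                       duration=T, n_neurons=N,
                       meta={"dt": dt, "seed": seed})


def estimate_effective_tau(
    params: LIFParams,
    state: StationaryState,
    J_impulse: float,
    n_trials: int = 240_000,
    T_trial: float = 60.0,
    dt: float = 0.05,
    seed: int = 0,
    fit_window: tuple[float, float] | None = None,
) -> float:
    """Effective kernel time constant from the single-neuron impulse response.

    Pairs of single-neuron simulations at the network working point share the
    same external noise realization; one member receives one extra synaptic
    impulse of weight ``J_impulse`` at a fixed time.  The trial-averaged
    difference of the spike responses estimates ``w h(t)``; the time constant
    of the matching exponential is the moment ratio integral/peak of the
    smoothed decaying flank.  Falls back to ``tau_m`` if the estimate is
    unusable.
    """
    p = params
    mu, sigma = state.mu, state.sigma
    rng = np.random.default_rng(seed)
    n_steps = int(round(T_trial / dt))
    t0_step = n_steps // 3
    e_m, e_s = math.exp(-dt / p.tau_m), math.exp(-dt / p.tau_s)
    eps = p.tau_s / (p.tau_s - p.tau_m)
    ref_steps = max(int(round(p.tau_r / dt)), 1)
    jump = p.tau_m / p.tau_s
    # synaptic current as an exact-update OU process around mu whose
    # white-noise limit reproduces the diffusion moments (mu, sigma^2):
    # stationary std sigma * sqrt(tau_m / (2 tau_s))
    s_eq = sigma * math.sqrt(p.tau_m / (2.0 * p.tau_s))
    kick = s_eq * math.sqrt(1.0 - e_s**2)

    psth = np.zeros(n_steps)
    batch = 4000
    for start in range(0, n_trials, batch):
        m = min(batch, n_trials - start)
        Vb = np.tile(rng.uniform(p.V_r, p.V_theta, size=m), (2, 1))
        Ib = np.tile(mu + s_eq * rng.standard_normal(m), (2, 1))
        refr = np.zeros((2, m), dtype=int)
        diff = np.zeros(n_steps)
        for k in range(n_steps):
            xi = rng.standard_normal(m)
            Ib = mu + (Ib - mu) * e_s + kick * xi
            if k == t0_step:
                Ib[1] += jump * J_impulse
            Vb = (Vb - eps * Ib) * e_m + eps * Ib * e_s
            clamped = refr > 0
            Vb[clamped] = p.V_r
            refr[clamped] -= 1
            spk = (Vb >= p.V_theta) & ~clamped
            Vb[spk] = p.V_r
            refr[spk] = ref_steps
            diff[k] += int(spk[1].sum()) - int(spk[0].sum())
        psth += diff
    resp = psth / (n_trials * dt)

    # smooth, then reduce the decaying flank to the time constant of the
    # matching single exponential by the moment estimator tau = integral/peak
    # (exact for a true exponential, robust to the trial-noise floor)
    width = max(int(round(0.5 / dt)), 1)
    sm = np.convolve(resp, np.ones(width) / width, mode="same")
    if fit_window is None:
        fit_window = (0.0, 12.0)
    lo = t0_step + int(round(fit_window[0] / dt))
    hi = min(t0_step + int(round(fit_window[1] / dt)), n_steps)
    seg = sm[lo:hi]
    if seg.size < 10 or seg.max() <= 0:
        return p.tau_m
    k_peak = int(np.argmax(seg))
    flank = seg[k_peak:]
    tau_eff = float(flank.sum() * dt / flank[0])
    if not (0.01 * p.tau_m < tau_eff < 5.0 * p.tau_m):
        return p.tau_m
    return tau_eff
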