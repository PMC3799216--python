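"""Closed-form covariance functions of delay-coupled linear rate models.

A network of linear rate units with exponential kernel ``h`` (time constant
``tau``), conduction delay ``d`` and white additive noise is an
Ornstein-Uhlenbeck system.  Depending on whether the noise enters on the
*input* side (``tau r' + r = w r(t-d) + x``, the binary-model class) or on the
*output* side (the transmitted signal is ``y = r + x``, the spiking-model
class), the cross spectrum is::

    input  : C(w) = (H_d^-1 - w)^-1  D  (H_d(-w)^-1 - w^T)^-1
    output : C(w) = (1 - H_d w)^-1   D  (1 - H_d(-w) w^T)^-1

with ``H_d`` the delayed transfer function and ``D`` the diagonal noise
matrix.  The poles of both spectra are the solutions of
``(1 + i z tau) e^{i z d} = L`` for each eigenvalue ``L`` of ``w`` and are
expressed through the branches of the Lambert-W function.

For the population-averaged 2x2 system (eigenvalues ``{0, L}``) the Fourier
back-transform is carried out exactly with the residue theorem, giving the
covariance at lag ``t >= 0`` as a combination of five scalar functions
``phi_0 .. phi_4``; negative lags follow from ``c(-t) = c(t)^T``.  For output
noise the result splits into a delta peak ``D delta(t)``, a symmetric
common-input term and an echo term that vanishes for ``|t| < d`` and jumps at
``|t| = d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.special

from .kernels import ExponentialKernel
from .network import ReducedNetwork

__all__ = [
    "NoisePlacement",
    "PoleSet",
    "CovFunction",
    "poles",
    "cross_spectrum",
    "phi_functions",
    "covariance_time_domain",
    "decompose_covariance",
    "numeric_inverse_ft",
    "single_unit_autocovariance",
]

#: default Lambert-W branch cutoff; the sum runs over branches |k| <= K_MAX_DEFAULT
K_MAX_DEFAULT = 20

_CHAR_TOL = 1e-10


@dataclass(frozen=True)
class NoisePlacement:
    """Location and strength of the additive white noise.

    ``placement`` is ``'input'`` (noise enters before the kernel; binary-model
    class) or ``'output'`` (noise added to the transmitted signal; spiking
    class).  ``rho2`` is the noise power density (units^2 * ms), a scalar for
    homogeneous noise or a per-unit array.
    """

    placement: Literal["input", "output"]
    rho2: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if self.placement not in ("input", "output"):
            raise ValueError("placement must be 'input' or 'output'")
        if np.any(np.asarray(self.rho2) < 0):
            raise ValueError("noise power rho2 must be >= 0")

    def D(self, n: int) -> np.ndarray:
        """Diagonal noise matrix for an ``n``-unit system."""
        rho2 = np.broadcast_to(np.asarray(self.rho2, dtype=float), (n,))
        return np.diag(rho2)


@dataclass
class PoleSet:
    """Poles of the propagator for one eigenvalue ``L`` of the connectivity."""

    poles: np.ndarray          # complex frequencies z_k, 1/ms
    branches: np.ndarray       # Lambert-W branch indices
    L: float
    kernel: ExponentialKernel

    @property
    def stable(self) -> bool:
        return bool(np.all(self.poles.imag > 0))

    def residuals(self) -> np.ndarray:
        """|characteristic equation| at each pole; ~0 by construction."""
        z = self.poles
        return np.abs(self.kernel.transfer_inverse(z) - self.L)


def poles(L: float, kernel: ExponentialKernel, k_max: int = K_MAX_DEFAULT) -> PoleSet:
    """Propagator poles ``z_k(L)`` of the delayed exponential kernel.

    For ``d > 0`` the characteristic equation ``(1 + i z tau) e^{i z d} = L``
    has infinitely many solutions ``z_k = i/tau - (i/d) W_k(L (d/tau) e^{d/tau})``,
    one per branch ``k`` of the Lambert-W function; branches ``|k| <= k_max``
    are returned.  For ``d = 0`` there is the single solution
    ``z = i (1 - L)/tau``.  Each root is Newton-polished on the characteristic
    equation.
    """
    tau, d = kernel.tau, kernel.d
    if d == 0.0:
        z = np.array([1j * (1.0 - L) / tau])
        return PoleSet(poles=z, branches=np.array([0]), L=L, kernel=kernel)

    x = L * d / tau * np.exp(d / tau)
    ks = np.arange(-k_max, k_max + 1)
    w = np.array([scipy.special.lambertw(x, k=int(k)) for k in ks])
    good = np.isfinite(w)
    ks, w = ks[good], w[good]
    z = 1j / tau - 1j / d * w

    # Newton polish: g(z) = (1 + i z tau) e^{i z d} - L
    for _ in range(50):
        e = np.exp(1j * z * d)
        g = (1.0 + 1j * z * tau) * e - L
        if np.all(np.abs(g) < 1e-13):
            break
        gp = 1j * tau * e + (1.0 + 1j * z * tau) * 1j * d * e
        step = g / gp
        z = z - step

    res = np.abs(kernel.transfer_inverse(z) - L)
    if np.any(res > _CHAR_TOL):
        warnings.warn("pole residual above tolerance after polishing", RuntimeWarning)
    return PoleSet(poles=z, branches=ks, L=L, kernel=kernel)


def _as_matrix_and_D(w, kernel, noise):
    if isinstance(w, ReducedNetwork):
        return w.M, w.D_bar, kernel
    M = np.asarray(w, dtype=float)
    return M, noise.D(M.shape[0]), kernel


def cross_spectrum(w, kernel: ExponentialKernel, noise: NoisePlacement, omegas) -> np.ndarray:
    """Matrix-valued cross spectrum ``C(omega)`` on a real frequency grid.

    ``w`` is a full weight matrix or a :class:`ReducedNetwork` (whose
    ``D_bar`` then overrides the noise amplitude).  Returns an array of shape
    ``(n_omega, N, N)``.
    """
    M, D, kernel = _as_matrix_and_D(w, kernel, noise)
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    N = M.shape[0]
    eye = np.eye(N)
    Hd_p = kernel.transfer(omegas, delayed=True)            # H_d(omega)
    Hd_m = kernel.transfer(-omegas, delayed=True)           # H_d(-omega)

    if noise.placement == "input":
        A = kernel.transfer_inverse(omegas)[:, None, None] * eye - M
        B = kernel.transfer_inverse(-omegas)[:, None, None] * eye - M.T
    else:
        A = eye - Hd_p[:, None, None] * M
        B = eye - Hd_m[:, None, None] * M.T

    dets = np.abs(np.linalg.det(A))
    scale = max(np.max(np.abs(M)), 1.0) ** N
    if np.any(dets < 1e-12 * scale):
        raise RuntimeError("pole on real axis: system at/beyond bifurcation")
    Ainv = np.linalg.inv(A)
    Binv = np.linalg.inv(B)
    return Ainv @ D @ Binv


def _f(omega, kernel: ExponentialKernel, L: float):
    """Propagator scalar f(omega) = 1 / (H_d(omega)^-1 - L)."""
    return 1.0 / (kernel.transfer_inverse(omega) - L)


@dataclass
class PhiFunctions:
    """The scalar building blocks of the reduced time-domain covariance.

    All functions are evaluated on the non-negative lag grid ``t``:

    - ``phi1``: common-input shape for output noise / autocovariance shape for
      input noise (Fourier pair of ``f(w) f(-w)``).
    - ``phi2``, ``phi3``: echo shapes for input noise.
    - ``phi4``: common-input shape for input noise.
    - ``phi0``: echo shape for output noise; identically zero for ``t < d``.

    ``truncation`` reports the relative weight of the largest-|k| branch pair
    in the residue sums (an upper estimate of the truncation remainder).
    """

    t: np.ndarray
    phi0: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray
    phi3: np.ndarray
    phi4: np.ndarray
    truncation: float


def phi_functions(
    L: float,
    kernel: ExponentialKernel,
    t_grid,
    k_max: int = K_MAX_DEFAULT,
) -> PhiFunctions:
    """Residue-theorem evaluation of ``phi_0 .. phi_4`` on ``t_grid >= 0``.

    Requires a stable system (all poles in the upper half plane) and
    ``|L|`` bounded away from zero (the balanced case ``L = 0`` with coupling
    produces a double kernel pole; use :func:`numeric_inverse_ft` there).
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("phi functions are defined on non-negative lags")
    tau, d = kernel.tau, kernel.d
    ps = poles(L, kernel, k_max=k_max)
    if not ps.stable:
        raise RuntimeError("unstable dynamics: pole in lower half plane")
    if abs(L) < 1e-8:
        # uncoupled limit: f = H_d, single kernel pole
        phi1 = np.exp(-t / tau) / (2.0 * tau)
        zero = np.zeros_like(t)
        return PhiFunctions(t=t, phi0=zero, phi1=phi1, phi2=zero.copy(),
                            phi3=zero.copy(), phi4=phi1.copy(), truncation=0.0)

    z = ps.poles                                   # (n_p,)
    e_izd = np.exp(1j * z * d)
    res_f = 1.0 / (1j * d * L + 1j * tau * e_izd)  # Res(f, z_k)
    f_mz = _f(-z, kernel, L)
    Hd_z = kernel.transfer(z, delayed=True)
    Hd_mz = kernel.transfer(-z, delayed=True)

    expzt = np.exp(1j * z[:, None] * t[None, :])   # (n_p, n_t)

    def _sum(coef):
        terms = (coef[:, None] * expzt)
        return terms.sum(axis=0)

    c1 = 1j * res_f * f_mz
    c2 = c1 * Hd_z
    c3 = c1 * Hd_mz
    c4 = c1 * Hd_z * Hd_mz

    # kernel-pole (z = i/tau) contributions
    f_ip = _f(1j / tau, kernel, L)      # f(i/tau)  = -1/L
    f_im = _f(-1j / tau, kernel, L)     # f(-i/tau) = 1/(2 e^{d/tau} - L)
    ff = (f_ip * f_im).real

    phi1 = _sum(c1)
    phi4 = _sum(c4) + ff * np.exp(-t / tau) / (2.0 * tau)
    phi3 = _sum(c3)

    # phi2: the printed residue sum holds for t >= d (upper contour); for
    # 0 <= t < d the contour closes below and the transform equals phi3(-t),
    # evaluated with the phi3 sum which is valid for all t > -d.
    phi2 = np.empty(t.size, dtype=complex)
    up = t >= d - 1e-9
    phi2[up] = (c2[:, None] * np.exp(1j * z[:, None] * t[None, up])).sum(axis=0) \
        + ff * np.exp((d - t[up]) / tau) / tau
    phi2[~up] = (c3[:, None] * np.exp(-1j * z[:, None] * t[None, ~up])).sum(axis=0)

    c0 = 1j * res_f
    phi0 = np.where(t >= d - 1e-9, _sum(c0), 0.0)

    # truncation diagnostic: weight of the outermost branch pair
    if z.size >= 3:
        order = np.argsort(np.abs(ps.branches))
        outer = order[-2:]
        num = np.abs(c1[outer][:, None] * expzt[outer]).sum()
        den = max(np.abs(phi1).sum(), 1e-300)
        trunc = float(num / den)
    else:
        trunc = 0.0

    # imaginary residue measures branch-truncation error away from t = d,
    # where the echo sums converge slowly by construction (jump point)
    away = np.abs(t - d) > 0.51 * max(tau / 100.0, 1e-6)
    imag_max = max(np.max(np.abs(p.imag[away]), initial=0.0)
                   for p in (phi1, phi2, phi3, phi4))
    if imag_max > 1e-3 * max(np.max(np.abs(phi1.real)), 1e-300):
        warnings.warn("phi functions have non-negligible imaginary part", RuntimeWarning)

    return PhiFunctions(t=t, phi0=phi0.real, phi1=phi1.real, phi2=phi2.real,
                        phi3=phi3.real, phi4=phi4.real, truncation=trunc)


@dataclass
class CovFunction:
    """Matrix-valued covariance function on a symmetric lag grid.

    ``blocks[k]`` is the matrix ``c(lags[k])`` (covariance density,
    units^2/ms); ``delta_weight`` is the coefficient matrix of a separate
    ``delta(t)`` contribution (never discretized onto the grid).
    """

    lags: np.ndarray
    blocks: np.ndarray
    delta_weight: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def block(self, a: int, b: int) -> np.ndarray:
        return self.blocks[:, a, b]

    def symmetry_error(self) -> float:
        """max |c(-t) - c(t)^T| over lag pairs present on the grid."""
        err = 0.0
        lag_index = {round(float(l), 9): k for k, l in enumerate(self.lags)}
        for k, l in enumerate(self.lags):
            j = lag_index.get(round(float(-l), 9))
            if j is not None:
                err = max(err, float(np.max(np.abs(self.blocks[j] - self.blocks[k].T))))
        return err

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"lag_ms": self.lags}
        n = self.blocks.shape[1]
        names = ["e", "i"] if n == 2 else [str(k) for k in range(n)]
        for a in range(n):
            for b in range(n):
                cols[f"c_{names[a]}{names[b]}"] = self.blocks[:, a, b]
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            if self.delta_weight is not None:
                fh.write("# delta_weight " +
                         " ".join(f"{v:.12g}" for v in np.ravel(self.delta_weight)) + "\n")
            for key, val in self.meta.items():
                fh.write(f"# {key} {val}\n")
            df.to_csv(fh, index=False)


def _abs_grid(t_grid):
    """Non-negative lag grid; |t| rounded so +t and -t map to the same node."""
    return np.unique(np.round(np.abs(np.asarray(t_grid, dtype=float)), 9))


def _mirror(t_grid, t_pos, c_pos):
    """Assemble c on a signed grid from the t>=0 solution via c(-t)=c(t)^T."""
    t_grid = np.asarray(t_grid, dtype=float)
    n = c_pos.shape[1]
    out = np.empty((t_grid.size, n, n))
    index = {v: k for k, v in enumerate(np.round(t_pos, 9))}
    for k, tval in enumerate(t_grid):
        key = round(abs(float(tval)), 9)
        j = index.get(key)
        if j is None:
            j = int(np.argmin(np.abs(t_pos - abs(tval))))
        out[k] = c_pos[j] if tval >= 0 else c_pos[j].T
    return out


def covariance_time_domain(
    net: ReducedNetwork,
    kernel: ExponentialKernel,
    noise: NoisePlacement,
    t_grid,
    k_max: int = K_MAX_DEFAULT,
) -> CovFunction:
    """Exact time-domain covariance of the reduced 2x2 system.

    For input noise (``t >= 0``, with ``B = M - L``)::

        c(t) = D phi1 + B D phi2 + D B^T phi3 + B D B^T phi4

    For output noise::

        c(t) = M D M^T phi1 + M D phi0 + D delta(t)

    both extended to negative lags by ``c(-t) = c(t)^T``.  ``D`` here is the
    reduced noise matrix ``net.D_bar``; the formulas hold for arbitrary
    diagonal ``D``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t_pos = _abs_grid(t_grid)
    M, D, L = net.M, net.D_bar, net.L

    if abs(L) < 1e-8 and np.max(np.abs(M)) > 1e-12:
        raise ValueError(
            "balanced coupling (L ~ 0) has a degenerate pole structure; "
            "use numeric_inverse_ft for this case")

    phis = phi_functions(L, kernel, t_pos, k_max=k_max)

    if noise.placement == "input":
        if abs(L) < 1e-8:
            c_pos = D[None] * phis.phi1[:, None, None]
        else:
            B = M - L * np.eye(2)
            c_pos = (D[None] * phis.phi1[:, None, None]
                     + (B @ D)[None] * phis.phi2[:, None, None]
                     + (D @ B.T)[None] * phis.phi3[:, None, None]
                     + (B @ D @ B.T)[None] * phis.phi4[:, None, None])
        delta_w = None
    else:
        c_pos = ((M @ D @ M.T)[None] * phis.phi1[:, None, None]
                 + (M @ D)[None] * phis.phi0[:, None, None])
        delta_w = D.copy()

    blocks = _mirror(t_grid, t_pos, c_pos)
    return CovFunction(lags=t_grid, blocks=blocks, delta_weight=delta_w,
                       meta={"L": L, "tau": kernel.tau, "d": kernel.d,
                             "noise": noise.placement, "k_max": k_max,
                             "truncation": phis.truncation})


def decompose_covariance(
    net: ReducedNetwork,
    kernel: ExponentialKernel,
    noise: NoisePlacement,
    t_grid,
    k_max: int = K_MAX_DEFAULT,
) -> dict:
    """Split the reduced covariance into delta, echo and common-input parts.

    Output noise: ``delta = D delta(t)``; ``echo`` is the propagated impulse of
    the sending unit (zero for ``|t| < d``, jump at ``|t| = d``); ``common``
    is the symmetric shared-input term.  Input noise: the ``phi1`` term plays
    the role of the delta part (it carries the autocovariance), the
    ``phi2``/``phi3`` terms are the echo and the ``phi4`` term the common
    input.  The three parts sum to :func:`covariance_time_domain` exactly.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    t_pos = _abs_grid(t_grid)
    M, D, L = net.M, net.D_bar, net.L
    phis = phi_functions(L, kernel, t_pos, k_max=k_max)
    zeros = np.zeros((t_pos.size, 2, 2))

    if noise.placement == "output":
        common = (M @ D @ M.T)[None] * phis.phi1[:, None, None]
        echo = (M @ D)[None] * phis.phi0[:, None, None]
        delta_blocks, delta_w = zeros, D.copy()
    else:
        B = M - L * np.eye(2)
        delta_blocks = D[None] * phis.phi1[:, None, None]
        echo = ((B @ D)[None] * phis.phi2[:, None, None]
                + (D @ B.T)[None] * phis.phi3[:, None, None])
        common = (B @ D @ B.T)[None] * phis.phi4[:, None, None]
        delta_w = None

    out = {}
    for name, c_pos, dw in (("delta_term", delta_blocks, delta_w),
                            ("echo_term", echo, None),
                            ("common_input_term", common, None)):
        out[name] = CovFunction(lags=t_grid, blocks=_mirror(t_grid, t_pos, c_pos),
                                delta_weight=dw, meta={"part": name})
    return out


def numeric_inverse_ft(
    omegas,
    spectrum,
    t_grid,
    constant_part=None,
    decay_tol: float = 5e-2,
) -> CovFunction:
    """Trapezoid-quadrature inverse Fourier transform of a sampled spectrum.

    Independent numerical route to the time-domain covariance,
    ``c(t) = (1/2pi) \\int C(w) e^{iwt} dw``.  A non-decaying constant part of
    the spectrum (the delta term of the output-noise solution) must be passed
    as ``constant_part``; it is subtracted before quadrature and stored as the
    delta weight of the result.
    """
    omegas = np.asarray(omegas, dtype=float)
    spec = np.asarray(spectrum, dtype=complex)
    if spec.ndim == 1:
        spec = spec[:, None, None]
    if constant_part is not None:
        spec = spec - np.asarray(constant_part, dtype=complex)[None]
    edge = max(np.max(np.abs(spec[0])), np.max(np.abs(spec[-1])))
    mid = np.max(np.abs(spec))
    if mid > 0 and edge > decay_tol * mid:
        raise ValueError(
            "spectrum does not decay on the grid; declare its constant part")
    t = np.asarray(t_grid, dtype=float)
    weights = np.gradient(omegas)
    wspec = spec * weights[:, None, None]
    integ = np.empty((t.size,) + spec.shape[1:], dtype=complex)
    for lo in range(0, t.size, 32):                  # chunked over lags
        phase = np.exp(1j * np.outer(t[lo:lo + 32], omegas))
        integ[lo:lo + 32] = np.tensordot(phase, wspec, axes=(1, 0))
    integ /= 2 * np.pi
    cw = None if constant_part is None else np.asarray(constant_part, dtype=float)
    return CovFunction(lags=t, blocks=integ.real, delta_weight=cw,
                       meta={"method": "trapezoid quadrature"})


def single_unit_autocovariance(rho2: float, tau: float, t) -> np.ndarray:
    """Autocovariance ``(rho2 / 2 tau) exp(-|t|/tau)`` of an uncoupled unit
    with input noise; also the weak-coupling approximation of the single-unit
    autocovariance in the network."""
    t = np.asarray(t, dtype=float)
    return rho2 / (2.0 * tau) * np.exp(-np.abs(t) / tau)
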