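"""Covariance and spectrum estimation from simulated activity.

Correlogram estimation is FFT-based with mean-product subtraction; standard
errors come from a segment bootstrap (the recording is cut into contiguous
segments, per-segment correlograms are resampled with replacement), which
remains valid under the temporal correlations of the data.  Delta peaks of
spiking data appear as mass ``rate/bin`` in the zero-lag bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .kernels import ExponentialKernel
from .linear_theory import NoisePlacement
from .lrm import RateTrajectory, simulate_lrm
from .network import ReducedNetwork

__all__ = [
    "CovEstimate",
    "estimate_covariance",
    "population_covariance",
    "mean_autocovariance",
    "power_spectrum",
    "empirical_decomposition",
    "augment_with_auxiliary",
]


@dataclass
class CovEstimate:
    """Estimated covariance on a symmetric lag grid with bootstrap errors."""

    lags: np.ndarray
    blocks: np.ndarray        # (n_lags, n, n)
    se: np.ndarray            # same shape
    bin_width: float
    n_pairs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def block(self, a: int, b: int) -> np.ndarray:
        return self.blocks[:, a, b]

    def to_csv(self, path) -> None:
        import pandas as pd

        n = self.blocks.shape[1]
        names = ["e", "i"] if n == 2 else [str(k) for k in range(n)]
        cols = {"lag_ms": self.lags}
        for a in range(n):
            for b in range(n):
                cols[f"c_{names[a]}{names[b]}"] = self.blocks[:, a, b]
        for a in range(n):
            for b in range(n):
                cols[f"se_{names[a]}{names[b]}"] = self.se[:, a, b]
        with open(path, "w") as fh:
            fh.write(f"# bin_ms {self.bin_width}\n")
            if self.n_pairs is not None:
                fh.write("# n_pairs " + " ".join(str(v) for v in np.ravel(self.n_pairs)) + "\n")
            pd.DataFrame(cols).to_csv(fh, index=False)


def _signals_from(data, bin_width, indices=None, mean=False):
    """Binned signal matrix/vector from any of the trajectory containers."""
    if isinstance(data, np.ndarray):
        sig = data if not mean else data[indices].mean(axis=0)
        return np.atleast_2d(sig)
    if isinstance(data, RateTrajectory):
        vals = data.values
        step = bin_width / data.dt
        if abs(step - round(step)) > 1e-9:
            raise ValueError("bin width must be a multiple of the sampling step")
        step = int(round(step))
        if step > 1:
            nb = vals.shape[1] // step
            vals = vals[:, : nb * step].reshape(vals.shape[0], nb, step).mean(axis=2)
        if indices is None:
            indices = np.arange(vals.shape[0])
        if mean:
            return np.atleast_2d(vals[indices].mean(axis=0))
        return vals[np.asarray(indices)]
    # SpikeTrains and BinaryTrajectory expose .binned
    return np.atleast_2d(data.binned(bin_width, indices=indices, mean=mean))


def _raw_cross_cov(X, n_lags, means):
    """Biased-normalization cross-covariance of rows of ``X`` via FFT.

    Returns array (2*n_lags+1, n, n) with entry ``[k, a, b] =
    <x_a(t + lag_k) x_b(t)>`` where lag_k runs from ``-n_lags`` to ``n_lags``.
    """
    n, Tb = X.shape
    Xc = X - means[:, None]
    nfft = int(2 ** np.ceil(np.log2(Tb + n_lags + 1)))
    F = np.fft.rfft(Xc, n=nfft)
    out = np.empty((2 * n_lags + 1, n, n))
    denom = Tb - np.abs(np.arange(-n_lags, n_lags + 1))
    for a in range(n):
        for b in range(n):
            prod = F[a] * np.conj(F[b])
            corr = np.fft.irfft(prod, n=nfft)
            pos = corr[: n_lags + 1]              # lags 0..n_lags
            neg = corr[nfft - n_lags:]            # lags -n_lags..-1
            out[:, a, b] = np.concatenate([neg, pos]) / denom
    return out


def _segmented_cov(X, bin_width, max_lag, n_segments, seed=0, n_boot=200):
    """Mean correlogram over segments plus bootstrap SE."""
    n, Tb = X.shape
    n_lags = int(round(max_lag / bin_width))
    seg_len = Tb // n_segments
    if seg_len <= 2 * n_lags:
        raise ValueError("max_lag too long for the segment length")
    means = X[:, : seg_len * n_segments].mean(axis=1)
    segs = np.empty((n_segments, 2 * n_lags + 1, n, n))
    for s in range(n_segments):
        seg = X[:, s * seg_len: (s + 1) * seg_len]
        segs[s] = _raw_cross_cov(seg, n_lags, means)
    est = segs.mean(axis=0)
    # one-step correction of the mean-subtraction bias: subtracting the
    # sample mean removes Cov(xbar_a, xbar_b) ~ (1/T) sum_l c(l) from every
    # lag; estimate that sum from the correlogram itself and add it back
    bias = est.sum(axis=0) / (seg_len * n_segments)
    est = est + bias[None]
    segs = segs + bias[None, None]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_segments, size=(n_boot, n_segments))
    boot = segs[idx].mean(axis=1)
    se = boot.std(axis=0, ddof=1)
    se = np.maximum(se, 1e-300)
    lags = np.arange(-n_lags, n_lags + 1) * bin_width
    return lags, est, se, segs


def estimate_covariance(
    data,
    bin_width: float,
    max_lag: float,
    n_segments: int = 20,
    indices=None,
    seed: int = 0,
) -> CovEstimate:
    """Auto-/cross-covariance matrix of a (small) set of signals.

    ``data`` may be a raw signal matrix, a :class:`RateTrajectory`, a
    ``BinaryTrajectory`` or ``SpikeTrains``; spike data are binned at
    ``bin_width`` first, so the zero-lag bin carries the delta mass
    ``rate/bin_width``.  By construction the estimate satisfies
    ``c(-t) = c(t)^T`` exactly.
    """
    X = _signals_from(data, bin_width, indices=indices)
    lags, est, se, segs = _segmented_cov(X, bin_width, max_lag, n_segments, seed=seed)
    return CovEstimate(lags=lags, blocks=est, se=se, bin_width=bin_width,
                       meta={"n_segments": n_segments, "segments": segs})


def population_covariance(
    data,
    labels,
    bin_width: float,
    max_lag: float,
    disjoint: bool = False,
    n_segments: int = 20,
    seed: int = 0,
) -> CovEstimate:
    """Block-averaged (2x2) covariance of an E/I network recording.

    The block average ``c_ab = (N_a N_b)^-1 sum_ij c_ij`` equals the
    covariance between the population-mean signals and is estimated from
    those.  With ``disjoint=True`` the single-neuron autocovariance is removed
    from the diagonal blocks, which then average only pairs ``i != j``.
    """
    labels = np.asarray(labels)
    idx_e = np.flatnonzero(labels == "e")
    idx_i = np.flatnonzero(labels == "i")
    if idx_e.size == 0 or idx_i.size == 0:
        raise ValueError("empty population block")
    sig_e = _signals_from(data, bin_width, indices=idx_e, mean=True)[0]
    sig_i = _signals_from(data, bin_width, indices=idx_i, mean=True)[0]
    X = np.vstack([sig_e, sig_i])
    lags, est, se, segs = _segmented_cov(X, bin_width, max_lag, n_segments, seed=seed)
    n_pairs = np.array([[idx_e.size**2, idx_e.size * idx_i.size],
                        [idx_e.size * idx_i.size, idx_i.size**2]])
    if disjoint:
        auto = mean_autocovariance(data, labels, bin_width, max_lag)
        for k, (na, ab) in enumerate(((idx_e.size, auto[0]), (idx_i.size, auto[1]))):
            est[:, k, k] = (na * est[:, k, k] - ab) / (na - 1)
            se[:, k, k] = na * se[:, k, k] / (na - 1)
        n_pairs[0, 0] = idx_e.size * (idx_e.size - 1)
        n_pairs[1, 1] = idx_i.size * (idx_i.size - 1)
    return CovEstimate(lags=lags, blocks=est, se=se, bin_width=bin_width,
                       n_pairs=n_pairs, meta={"disjoint": disjoint,
                                              "n_segments": n_segments,
                                              "segments": segs})


def mean_autocovariance(data, labels, bin_width, max_lag, batch: int = 64):
    """Per-population mean single-neuron autocovariance (one array per pop)."""
    labels = np.asarray(labels)
    n_lags = int(round(max_lag / bin_width))
    out = []
    for lab in ("e", "i"):
        idx = np.flatnonzero(labels == lab)
        acc = np.zeros(2 * n_lags + 1)
        for start in range(0, idx.size, batch):
            sel = idx[start: start + batch]
            X = _signals_from(data, bin_width, indices=sel)
            means = X.mean(axis=1)
            cc = _raw_cross_cov_diag(X, n_lags, means)
            acc += cc.sum(axis=0)
        out.append(acc / idx.size)
    return out


def _raw_cross_cov_diag(X, n_lags, means):
    """Autocovariances only (rows of X), shape (n, 2*n_lags+1)."""
    n, Tb = X.shape
    Xc = X - means[:, None]
    nfft = int(2 ** np.ceil(np.log2(Tb + n_lags + 1)))
    F = np.fft.rfft(Xc, n=nfft)
    corr = np.fft.irfft(F * np.conj(F), n=nfft)
    denom = Tb - np.abs(np.arange(-n_lags, n_lags + 1))
    pos = corr[:, : n_lags + 1]
    neg = corr[:, nfft - n_lags:]
    return np.concatenate([neg, pos], axis=1) / denom


def power_spectrum(signal, dt: float, nperseg: int | None = None):
    """Welch-averaged two-sided power spectral density of one signal.

    Returns ``(omega, C)`` with angular frequency ``omega`` in 1/ms and ``C``
    normalized to the convention ``C(omega) = int c(t) exp(-i omega t) dt``,
    so a white signal of covariance density ``rho2 delta(t)`` gives
    ``C = rho2``.
    """
    signal = np.asarray(signal, dtype=float)
    if nperseg is None:
        nperseg = min(signal.size, 4096)
    f, psd = scipy.signal.welch(signal, fs=1.0 / dt, nperseg=nperseg,
                                detrend="constant")
    omega = 2.0 * np.pi * f
    C = psd / 2.0                       # one-sided -> two-sided density in f
    C[0] = psd[0]
    return omega, C


def augment_with_auxiliary(W: np.ndarray, copies: int = 1):
    """Append read-only copies of every unit to a weight matrix.

    Each auxiliary unit receives the same incoming weights as its original
    (identical input statistics) but projects nowhere; the covariance among
    auxiliary units measures the common-input part of the full covariance.
    Returns ``(W_aug, aux_slices)`` where ``aux_slices[k]`` indexes the k-th
    copy block.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    m = n * (1 + copies)
    W_aug = np.zeros((m, m))
    W_aug[:n, :n] = W
    slices = []
    for k in range(copies):
        lo = n * (1 + k)
        W_aug[lo: lo + n, :n] = W
        slices.append(slice(lo, lo + n))
    return W_aug, slices


def empirical_decomposition(
    net,
    kernel: ExponentialKernel,
    noise: NoisePlacement,
    T: float,
    dt: float | None = None,
    seed: int = 0,
    bin_width: float | None = None,
    max_lag: float = 50.0,
    n_segments: int = 20,
) -> dict:
    """Echo / common-input split of an LRM covariance by direct simulation.

    The system is augmented with two auxiliary copies per unit (read-only,
    independent noise): the covariance between distinct auxiliary copies is
    the common-input part; the echo part is the difference between the full
    covariance and the common part, so the two parts sum to the full estimate
    exactly.  ``net`` is a :class:`ReducedNetwork` or a weight matrix.
    """
    if isinstance(net, ReducedNetwork):
        W = net.M
        rho2_vec = np.diag(net.D_bar)
    else:
        W = np.asarray(net, dtype=float)
        rho2_vec = np.broadcast_to(np.asarray(noise.rho2, dtype=float), (W.shape[0],))
    n = W.shape[0]
    W_aug, aux = augment_with_auxiliary(W, copies=2)
    rho2_aug = np.concatenate([rho2_vec] * 3)
    noise_aug = NoisePlacement(noise.placement, rho2_aug)
    traj = simulate_lrm(W_aug, kernel, noise_aug, T=T, dt=dt, seed=seed)
    if bin_width is None:
        bin_width = traj.dt
    X_main = _signals_from(traj, bin_width, indices=np.arange(n))
    X_a1 = _signals_from(traj, bin_width, indices=np.arange(aux[0].start, aux[0].stop))
    X_a2 = _signals_from(traj, bin_width, indices=np.arange(aux[1].start, aux[1].stop))

    lags, full, se_full, _ = _segmented_cov(X_main, bin_width, max_lag, n_segments, seed=seed)
    # cross-covariance between the two independent aux copies: common input only
    Xc = np.vstack([X_a1, X_a2])
    lags2, both, se_both, _ = _segmented_cov(Xc, bin_width, max_lag, n_segments, seed=seed)
    common = 0.5 * (both[:, :n, n:] + both[:, n:, :n])
    se_common = 0.5 * (se_both[:, :n, n:] + se_both[:, n:, :n])
    echo = full - common
    se_echo = np.sqrt(se_full**2 + se_common**2)
    mk = lambda b, s: CovEstimate(lags=lags, blocks=b, se=s, bin_width=bin_width)
    return {
        "full": mk(full, se_full),
        "common_input_estimate": mk(common, se_common),
        "echo_estimate": mk(echo, se_echo),
    }
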