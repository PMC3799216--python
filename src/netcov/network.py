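"""Random excitatory/inhibitory connectivity and its population-averaged reduction.

A network of ``N_e`` excitatory and ``N_i = gamma*N_e`` inhibitory neurons is
wired as an Erdos-Renyi-like random graph with connection probability ``p``,
either with *fixed in-degree* (every neuron receives exactly ``K = p*N_e``
excitatory and ``gamma*K`` inhibitory synapses) or *fixed out-degree* (every
neuron sends exactly that many synapses to each population).  Excitatory
synapses carry weight ``w``, inhibitory ones ``-g*w``.

Averaging the dynamics over the two populations replaces the ``N x N`` weight
matrix by the 2x2 matrix::

    M = K*w * [[1, -gamma*g],
               [1, -gamma*g]]

whose eigenvalues are 0 and ``L = K*w*(1 - gamma*g)``.  The reduction is exact
for fixed out-degree and holds in expectation for fixed in-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.sparse as sps

__all__ = [
    "NetworkSpec",
    "ConnectivityMatrix",
    "ReducedNetwork",
    "build_random_network",
    "reduce_network",
    "reduce_from_weights",
    "spectral_radius",
    "write_edge_list",
    "read_edge_list",
]

#: store the weight matrix densely below this many neurons, sparsely above
DENSE_LIMIT = 2000


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the random E/I network.

    ``K = round(p*N_e)`` and ``gamma_K = round(gamma*p*N_e)`` so the degree
    invariants are exact integers.
    """

    N_e: int
    gamma: float
    p: float
    w: float
    g: float
    degree_mode: Literal["fixed_in", "fixed_out"] = "fixed_in"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_e < 1:
            raise ValueError("N_e must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("connection probability p must lie in [0, 1]")
        if self.g < 0:
            raise ValueError("inhibition factor g must be >= 0")
        n_i = self.gamma * self.N_e
        if abs(n_i - round(n_i)) > 1e-9:
            raise ValueError("gamma * N_e must be an integer")
        if self.degree_mode not in ("fixed_in", "fixed_out"):
            raise ValueError("degree_mode must be 'fixed_in' or 'fixed_out'")

    @property
    def N_i(self) -> int:
        return int(round(self.gamma * self.N_e))

    @property
    def N(self) -> int:
        return self.N_e + self.N_i

    @property
    def K(self) -> int:
        return int(round(self.p * self.N_e))

    @property
    def gamma_K(self) -> int:
        return int(round(self.gamma * self.p * self.N_e))


@dataclass
class ConnectivityMatrix:
    """Signed weight matrix with population labels.

    ``weights[i, j]`` couples source ``j`` to target ``i``.  ``pop_labels`` is a
    per-neuron array of ``'e'`` / ``'i'``.
    """

    weights: np.ndarray | sps.spmatrix
    pop_labels: np.ndarray

    @property
    def N(self) -> int:
        return self.weights.shape[0]

    @property
    def exc_indices(self) -> np.ndarray:
        return np.flatnonzero(self.pop_labels == "e")

    @property
    def inh_indices(self) -> np.ndarray:
        return np.flatnonzero(self.pop_labels == "i")

    def toarray(self) -> np.ndarray:
        if sps.issparse(self.weights):
            return self.weights.toarray()
        return np.asarray(self.weights)


@dataclass
class ReducedNetwork:
    """2x2 population-averaged system.

    ``M`` has identical rows, eigenvalues ``{0, L}``.  ``D_bar`` is the noise
    matrix of the population-averaged fluctuations; for homogeneous per-neuron
    noise power ``rho2`` it equals ``rho2 * diag(1/N_e, 1/N_i)``.
    """

    M: np.ndarray
    D_bar: np.ndarray
    L: float
    K: int
    N_e: int = 0
    N_i: int = 0

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.D_bar = np.asarray(self.D_bar, dtype=float)


def _sample_sources(rng, pool: np.ndarray, k: int) -> np.ndarray:
    if k > pool.size:
        raise ValueError("degree exceeds population size")
    return rng.permutation(pool)[:k]


def build_random_network(spec: NetworkSpec) -> ConnectivityMatrix:
    """Draw a random E/I weight matrix with exact fixed in- or out-degree.

    Sources (targets) are sampled without replacement within each population,
    excluding self-connections.  Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    N_e, N_i, N = spec.N_e, spec.N_i, spec.N
    K, gK = spec.K, spec.gamma_K
    labels = np.array(["e"] * N_e + ["i"] * N_i)
    exc = np.arange(N_e)
    inh = np.arange(N_e, N)

    dense = N <= DENSE_LIMIT
    if dense:
        W = np.zeros((N, N))
    else:
        W = sps.lil_matrix((N, N))

    w_e, w_i = spec.w, -spec.g * spec.w
    if spec.degree_mode == "fixed_in":
        # every row (target) picks K excitatory and gamma*K inhibitory sources
        for i in range(N):
            src_e = _sample_sources(rng, exc[exc != i], K)
            src_i = _sample_sources(rng, inh[inh != i], gK)
            W[i, src_e] = w_e
            W[i, src_i] = w_i
    else:
        # every column (source) picks K excitatory and gamma*K inhibitory targets
        for j in range(N):
            tgt_e = _sample_sources(rng, exc[exc != j], K)
            tgt_i = _sample_sources(rng, inh[inh != j], gK)
            wj = w_e if j < N_e else w_i
            W[tgt_e, j] = wj
            W[tgt_i, j] = wj

    if not dense:
        W = W.tocsr()
    return ConnectivityMatrix(W, labels)


def reduce_network(spec: NetworkSpec, rho2: float) -> ReducedNetwork:
    """Population-averaged 2x2 system of a homogeneous E/I network."""
    gg = spec.gamma * spec.g
    M = spec.K * spec.w * np.array([[1.0, -gg], [1.0, -gg]])
    L = spec.K * spec.w * (1.0 - gg)
    n_i = max(spec.N_i, 1)  # gamma = 0 degenerates to a one-population system
    D_bar = rho2 * np.diag([1.0 / spec.N_e, 1.0 / n_i])
    if spec.N_i == 0:
        D_bar[1, 1] = 0.0
    return ReducedNetwork(M=M, D_bar=D_bar, L=L, K=spec.K, N_e=spec.N_e, N_i=spec.N_i)


def reduce_from_weights(
    N_e: int,
    gamma: float,
    K: int,
    w_exc: float,
    w_inh: float,
    rho2,
) -> ReducedNetwork:
    """Reduced system for generalized effective weights.

    Used by the nonlinear-model mappings where excitatory and inhibitory
    effective weights are not related by a single factor ``-g`` (e.g. the LIF
    susceptibility ``alpha*J + beta*J**2``).  ``rho2`` may be a scalar
    (homogeneous noise) or a length-2 array of per-population noise powers.
    """
    N_i = int(round(gamma * N_e))
    gK = int(round(gamma * K))
    row = np.array([K * w_exc, gK * w_inh])
    M = np.vstack([row, row])
    L = float(row.sum())
    rho2 = np.broadcast_to(np.asarray(rho2, dtype=float), (2,))
    n_i = max(N_i, 1)
    D_bar = np.diag([rho2[0] / N_e, rho2[1] / n_i if N_i > 0 else 0.0])
    return ReducedNetwork(M=M, D_bar=D_bar, L=L, K=K, N_e=N_e, N_i=N_i)


def spectral_radius(spec: NetworkSpec) -> float:
    """Radius of the circle confining the bulk eigenvalues of the random matrix.

    ``w * sqrt(N_e * p * (1-p) * (1 + gamma*g**2))``; the reduced eigenvalue
    ``L`` sits outside this bulk.
    """
    return spec.w * np.sqrt(spec.N_e * spec.p * (1.0 - spec.p) * (1.0 + spec.gamma * spec.g**2))


def write_edge_list(conn: ConnectivityMatrix, path, labels_path=None) -> None:
    """Write connectivity as a 3-column edge list ``target source weight``.

    Ids are 0-based.  A population-label sidecar (one label per line) is
    written to ``labels_path`` (default: ``path`` + ``.labels``).
    """
    W = conn.weights.tocoo() if sps.issparse(conn.weights) else None
    if W is not None:
        tgt, src, val = W.row, W.col, W.data
    else:
        tgt, src = np.nonzero(conn.weights)
        val = conn.weights[tgt, src]
    arr = np.column_stack([tgt, src, val])
    np.savetxt(path, arr, fmt=["%d", "%d", "%.12g"], header="target_id source_id weight")
    if labels_path is None:
        labels_path = str(path) + ".labels"
    with open(labels_path, "w") as fh:
        fh.write("\n".join(conn.pop_labels) + "\n")


def read_edge_list(path, labels_path=None) -> ConnectivityMatrix:
    if labels_path is None:
        labels_path = str(path) + ".labels"
    with open(labels_path) as fh:
        labels = np.array([ln.strip() for ln in fh if ln.strip()])
    N = labels.size
    arr = np.loadtxt(path, ndmin=2)
    W = np.zeros((N, N)) if N <= DENSE_LIMIT else sps.lil_matrix((N, N))
    if arr.size:
        tgt = arr[:, 0].astype(int)
        src = arr[:, 1].astype(int)
        W[tgt, src] = arr[:, 2]
    if sps.issparse(W):
        W = W.tocsr()
    return ConnectivityMatrix(W, labels)
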