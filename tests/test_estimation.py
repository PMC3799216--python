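import numpy as np
import pytest

from netcov import ExponentialKernel, NoisePlacement, simulate_lrm
from netcov.estimation import (
    empirical_decomposition,
    estimate_covariance,
    mean_autocovariance,
    population_covariance,
    power_spectrum,
)
from netcov.linear_theory import decompose_covariance, poles, single_unit_autocovariance
from netcov.network import ReducedNetwork


def _reduced(L=-1.72, gamma=0.25, g=5.0, N_e=100):
    Kw = L / (1 - gamma * g)
    M = Kw * np.array([[1, -gamma * g], [1, -gamma * g]])
    D = np.diag([1.0 / N_e, 1.0 / (gamma * N_e)])
    return ReducedNetwork(M=M, D_bar=D, L=L, K=10, N_e=N_e, N_i=int(gamma * N_e))


def test_estimate_is_exactly_lag_symmetric():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((3, 4000))
    est = estimate_covariance(X, 1.0, 20.0, n_segments=10)
    for k, lag in enumerate(est.lags):
        j = np.argmin(np.abs(est.lags + lag))
        assert np.allclose(est.blocks[j], est.blocks[k].T, atol=1e-12)


def test_uncoupled_oup_matches_analytic_autocovariance():
    kern = ExponentialKernel(10.0, 0.0)
    traj = simulate_lrm(np.zeros((1, 1)), kern, NoisePlacement("input", 1.0),
                        T=2e5, dt=0.1, seed=1)
    est = estimate_covariance(traj, 0.1, 40.0)
    th = single_unit_autocovariance(1.0, 10.0, est.lags)
    z = np.abs(est.block(0, 0) - th) / est.se[:, 0, 0]
    assert (z < 3).mean() > 0.97


def test_disjoint_average_removes_autocovariance_exactly():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((8, 4000))
    labels = np.array(["e"] * 6 + ["i"] * 2)
    full = population_covariance(X, labels, 1.0, 10.0, n_segments=8)
    disj = population_covariance(X, labels, 1.0, 10.0, disjoint=True, n_segments=8)
    auto_e, _ = mean_autocovariance(X, labels, 1.0, 10.0)
    # c_disjoint = (N c_full - mean_auto) / (N - 1) on the diagonal block
    recon = (6 * full.blocks[:, 0, 0] - auto_e) / 5
    assert np.allclose(disj.blocks[:, 0, 0], recon, atol=1e-12)
    assert np.allclose(disj.blocks[:, 0, 1], full.blocks[:, 0, 1], atol=1e-12)


def test_population_sum_consistency():
    # autocovariance of the summed activity equals the size-weighted block sum
    rng = np.random.default_rng(3)
    X = rng.standard_normal((6, 3000)) + 0.3 * rng.standard_normal((1, 3000))
    labels = np.array(["e"] * 4 + ["i"] * 2)
    est = population_covariance(X, labels, 1.0, 8.0, n_segments=6)
    total = X[:4].sum(axis=0) + X[4:].sum(axis=0)
    est_tot = estimate_covariance(total[None, :], 1.0, 8.0, n_segments=6)
    sizes = np.array([4, 2])
    combo = np.einsum("a,kab,b->k", sizes, est.blocks, sizes)
    assert np.allclose(est_tot.blocks[:, 0, 0], combo, atol=1e-10)


def test_power_spectrum_of_white_noise_is_flat():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(200_000)
    om, C = power_spectrum(x, dt=1.0)
    inner = (om > 0.3) & (om < 2.8)
    assert abs(C[inner].mean() - 1.0) < 0.05
    assert C[inner].std() / C[inner].mean() < 0.2


def test_power_spectrum_peak_at_pole_frequency():
    # underdamped delayed feedback: spectral peak at the least-damped pole
    L, tau, d = -1.1, 10.0, 8.0
    kern = ExponentialKernel(tau, d)
    ps = poles(L, kern)
    lead = ps.poles[np.argmin(ps.poles.imag)]
    assert ps.stable and abs(lead.real) > 2 * lead.imag  # underdamped fixture
    net = _reduced(L=L)
    traj = simulate_lrm(net, kern, NoisePlacement("output", 1.0), T=2e5,
                        dt=0.1, seed=7)
    om, C = power_spectrum(traj.values.sum(axis=0), dt=0.1, nperseg=8192)
    sel = om > 0.02
    peak = om[sel][np.argmax(C[sel])]
    assert abs(peak - abs(lead.real)) <= 3 * (om[1] - om[0])


def test_decomposition_conservation_and_analytic_match():
    net = _reduced()
    kern = ExponentialKernel(10.0, 3.0)
    noise = NoisePlacement("output", 1.0)
    dec = empirical_decomposition(net, kern, noise, T=2e5, dt=0.1, seed=5,
                                  max_lag=40.0)
    # estimator identity: parts sum to the full estimate exactly
    resid = np.abs(dec["common_input_estimate"].blocks
                   + dec["echo_estimate"].blocks - dec["full"].blocks)
    assert resid.max() < 1e-14
    # the common part matches the analytic common-input term
    parts = decompose_covariance(net, kern, noise, dec["full"].lags)
    z = (np.abs(dec["common_input_estimate"].blocks
                - parts["common_input_term"].blocks)
         / dec["common_input_estimate"].se)
    assert (z < 3).mean() > 0.95
    # echo estimate vanishes below the delay (delta bin excluded)
    m = (np.abs(dec["full"].lags) > 0.11) & (np.abs(dec["full"].lags) < 2.89)
    ze = np.abs(dec["echo_estimate"].blocks[m]) / dec["echo_estimate"].se[m]
    assert (ze < 3).mean() > 0.95


def test_uncoupled_system_has_no_echo():
    net = ReducedNetwork(M=np.zeros((2, 2)), D_bar=np.diag([0.01, 0.04]),
                         L=0.0, K=0, N_e=100, N_i=25)
    kern = ExponentialKernel(10.0, 3.0)
    dec = empirical_decomposition(net, kern, NoisePlacement("input", 1.0),
                                  T=1e5, dt=0.1, seed=6, max_lag=30.0)
    # pairwise (off-diagonal) echo vanishes; the diagonal of full - common
    # retains the unit's own-noise autocovariance by construction
    ze = (np.abs(dec["echo_estimate"].blocks[:, 0, 1])
          / dec["echo_estimate"].se[:, 0, 1])
    zi = (np.abs(dec["echo_estimate"].blocks[:, 1, 0])
          / dec["echo_estimate"].se[:, 1, 0])
    assert (np.concatenate([ze, zi]) < 3).mean() > 0.95


def test_error_estimates_shrink_with_duration():
    kern = ExponentialKernel(10.0, 0.0)
    ses = []
    for T in (4e4, 8e4):
        se_runs = []
        for seed in range(6):
            traj = simulate_lrm(np.zeros((1, 1)), kern, NoisePlacement("input", 1.0),
                                T=T, dt=0.2, seed=seed)
            est = estimate_covariance(traj, 0.2, 20.0)
            se_runs.append(est.se.mean())
        ses.append(np.mean(se_runs))
    ratio = ses[1] / ses[0]
    assert abs(ratio - 1 / np.sqrt(2)) < 0.2 * (1 / np.sqrt(2))
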