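import math

import numpy as np
import pytest
import scipy.stats

from netcov import (
    ExponentialKernel,
    GainParams,
    NetworkSpec,
    NoisePlacement,
    covariance_time_domain,
    effective_slope,
    map_binary_to_lrm,
    simulate_binary,
    working_point,
)
from netcov.binary import WorkingPoint, _gauss_avg
from netcov.estimation import estimate_covariance


def _spec(**kw):
    base = dict(N_e=400, gamma=0.25, p=0.5, w=0.025, g=8.0, degree_mode="fixed_in")
    base.update(kw)
    return NetworkSpec(**base)


class TestWorkingPoint:
    def test_uncoupled_network_sits_at_one_half(self):
        wp = working_point(_spec(w=0.0), 0.0, GainParams(0.7))
        assert np.isclose(wp.a, 0.5)
        assert wp.mu == 0.0 and wp.sigma2 == 0.0

    def test_fixed_point_reinserts(self):
        gain = GainParams(0.5)
        spec = _spec()
        wp = working_point(spec, 0.025, gain)
        mu = spec.K * 0.025 * (1 - spec.gamma * spec.g) * wp.a
        s2 = spec.K * 0.025**2 * (1 + spec.gamma * spec.g**2) * wp.a * (1 - wp.a)
        assert np.isclose(_gauss_avg(gain.phi, mu, math.sqrt(s2)), wp.a, atol=1e-8)
        assert np.isclose(wp.mu, mu) and np.isclose(wp.sigma2, s2)

    def test_balanced_case_against_bisection_oracle(self):
        # gamma g = 1 makes mu = 0; a solves a = <phi>_{N(0, sigma(a))}
        gain = GainParams(2.0)
        spec = _spec(gamma=0.25, g=4.0, w=0.2)
        wp = working_point(spec, 0.2, gain)
        assert abs(wp.mu) < 1e-12

        def F(a):
            s = math.sqrt(max(spec.K * 0.04 * (1 + 0.25 * 16) * a * (1 - a), 0))
            return _gauss_avg(gain.phi, 0.0, s) - a

        lo, hi = 1e-9, 1 - 1e-9
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if F(lo) * F(mid) <= 0:
                hi = mid
            else:
                lo = mid
        assert np.isclose(wp.a, 0.5 * (lo + hi), atol=1e-7)


class TestEffectiveSlope:
    def test_degenerate_spread_recovers_slope_at_mean(self):
        gain = GainParams(0.8)
        wp = WorkingPoint(a=0.4, mu=0.3, sigma2=0.0)
        at = effective_slope(gain, wp, "at_mean")
        ga = effective_slope(gain, wp, "gaussian_avg")
        expected = 0.4 * 0.8 / math.cosh(0.8 * 0.3) ** 2 * 1.25  # (beta/2) sech^2
        assert np.isclose(at, 0.5 * 0.8 / math.cosh(0.8 * 0.3) ** 2)
        assert np.isclose(ga, at)

    def test_hard_threshold_limit_is_gaussian_density(self):
        wp = WorkingPoint(a=0.5, mu=0.0, sigma2=0.25)
        ga = effective_slope(GainParams(np.inf), wp, "gaussian_avg")
        assert np.isclose(ga, 1.0 / (0.5 * math.sqrt(2 * math.pi)))

    def test_gaussian_average_against_monte_carlo(self):
        gain = GainParams(1.0)
        wp = WorkingPoint(a=0.5, mu=0.2, sigma2=0.25)
        rng = np.random.default_rng(3)
        draws = wp.mu + wp.sigma * rng.standard_normal(2_000_000)
        mc = gain.phi_prime(draws).mean()
        se = gain.phi_prime(draws).std() / math.sqrt(draws.size)
        assert abs(effective_slope(gain, wp, "gaussian_avg") - mc) < 3 * se


def test_mapping_noise_amplitude():
    # rho2 = 2 tau a (1-a): a = 1/2, tau = 10 -> 5
    wp = WorkingPoint(a=0.5, mu=0.0, sigma2=0.1)
    lin = map_binary_to_lrm(_spec(), 0.025, wp, 0.1, 10.0, 3.0)
    assert np.isclose(lin.noise.rho2, 5.0)
    assert lin.noise.placement == "input"
    # beta_eff = 0 switches the coupling off
    lin0 = map_binary_to_lrm(_spec(), 0.025, wp, 0.0, 10.0, 3.0)
    assert np.allclose(lin0.reduced.M, 0.0)


class TestSimulation:
    def test_single_neuron_stationary_activity(self):
        traj = simulate_binary(np.zeros((1, 1)), GainParams(1.0), 10.0, 0.0,
                               T=2e5, seed=1)
        a = traj.binned(1.0).mean()
        # flips form a renewal process; 3 SE with a generous correlation factor
        assert abs(a - 0.5) < 0.02

    def test_single_neuron_autocovariance(self):
        traj = simulate_binary(np.zeros((1, 1)), GainParams(1.0), 10.0, 0.0,
                               T=4e5, seed=2)
        est = estimate_covariance(traj, 1.0, 40.0)
        th = 0.25 * np.exp(-np.abs(est.lags) / 10.0)
        z = np.abs(est.block(0, 0) - th) / est.se[:, 0, 0]
        assert (z < 3).mean() > 0.95

    def test_flip_intervals_exponential(self):
        # an uncoupled neuron at a = 1/2 flips at rate 1/(2 tau); the
        # inter-flip intervals are exponential with mean 2 tau
        tau = 10.0
        traj = simulate_binary(np.zeros((1, 1)), GainParams(1.0), tau, 0.0,
                               T=3e5, seed=4)
        iv = np.diff(traj.flip_times)
        assert abs(iv.mean() - 2 * tau) < 3 * iv.std() / math.sqrt(iv.size)
        ks = scipy.stats.kstest(iv, "expon", args=(0, iv.mean()))
        assert ks.pvalue > 0.01

    def test_seed_reproducibility(self):
        J = np.array([[0.0, 0.3], [0.3, 0.0]])
        a = simulate_binary(J, GainParams(0.5), 10.0, 2.0, T=2e3, seed=5)
        b = simulate_binary(J, GainParams(0.5), 10.0, 2.0, T=2e3, seed=5)
        assert np.array_equal(a.flip_times, b.flip_times)
        assert np.array_equal(a.flip_ids, b.flip_ids)


class TestTheoryIdentities:
    def test_covariance_satisfies_delay_ode(self, fig_kernel):
        # tau dc/du + c(u) = M c(u - d) for u > d on the mapped solution
        L, gamma, g = -1.0, 0.25, 5.0
        Kw = L / (1 - gamma * g)
        M = Kw * np.array([[1, -gamma * g], [1, -gamma * g]])
        from netcov.network import ReducedNetwork

        net = ReducedNetwork(M=M, D_bar=np.diag([0.01, 0.04]), L=L, K=10)
        dt = 0.05
        t = np.arange(-80, 80.0001, dt)
        c = covariance_time_domain(net, fig_kernel, NoisePlacement("input"), t).blocks
        pos = np.flatnonzero((t > fig_kernel.d + 1) & (t < 60))
        dc = (c[pos + 1] - c[pos - 1]) / (2 * dt)
        lhs = 10.0 * dc + c[pos]
        rhs = np.einsum("ab,kbc->kac", M, c[pos - int(round(fig_kernel.d / dt))])
        assert np.abs(lhs - rhs).max() < 1e-4 * np.abs(c).max()

    def test_boundary_condition_at_zero_lag(self, fig_kernel):
        # 2 c(0) = M c(-d) + (M c(-d))^T + D/tau (truncation-limited accuracy)
        L, gamma, g = -1.0, 0.25, 5.0
        Kw = L / (1 - gamma * g)
        M = Kw * np.array([[1, -gamma * g], [1, -gamma * g]])
        from netcov.network import ReducedNetwork

        D = np.diag([0.01, 0.04])
        net = ReducedNetwork(M=M, D_bar=D, L=L, K=10)
        t = np.array([-fig_kernel.d, 0.0, fig_kernel.d])
        c = covariance_time_domain(net, fig_kernel, NoisePlacement("input"), t,
                                   k_max=80).blocks
        resid = 2 * c[1] - M @ c[0] - (M @ c[0]).T - D / fig_kernel.tau
        assert np.abs(resid).max() < 2e-5
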