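import numpy as np
import pytest

from netcov import ExponentialKernel, NoisePlacement
from netcov.linear_theory import (
    covariance_time_domain,
    cross_spectrum,
    decompose_covariance,
    numeric_inverse_ft,
    phi_functions,
    poles,
    single_unit_autocovariance,
)
from netcov.network import ReducedNetwork


def _make_net(L, gamma=0.25, g=5.0, N_e=1000):
    Kw = L / (1.0 - gamma * g)
    M = Kw * np.array([[1.0, -gamma * g], [1.0, -gamma * g]])
    D = np.diag([1.0 / N_e, 1.0 / (gamma * N_e)])
    return ReducedNetwork(M=M, D_bar=D, L=L, K=100, N_e=N_e, N_i=int(gamma * N_e))


class TestPoles:
    def test_instantaneous_coupling_closed_form(self):
        ps = poles(0.5, ExponentialKernel(10.0, 0.0))
        assert ps.poles.size == 1
        assert np.isclose(ps.poles[0], 0.05j, atol=1e-14)

    def test_zero_eigenvalue_gives_kernel_pole(self):
        for d in (0.0, 3.0):
            ps = poles(0.0, ExponentialKernel(10.0, d))
            assert np.any(np.isclose(ps.poles, 0.1j, atol=1e-12))

    def test_reference_parameters_satisfy_characteristic_equation(self, fig_kernel):
        ps = poles(-1.72, fig_kernel)
        assert ps.poles.size == 41
        assert ps.residuals().max() < 1e-10
        assert ps.stable

    def test_random_suite_residuals(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            L = rng.uniform(-5, 0.9)
            kern = ExponentialKernel(rng.uniform(1, 50), rng.uniform(0, 10))
            worst = max(worst, poles(L, kern).residuals().max())
        assert worst < 1e-10

    def test_newton_cross_check(self, fig_kernel):
        # independent 2-D Newton on the characteristic equation, seeded on a grid
        L = -1.72
        tau, d = fig_kernel.tau, fig_kernel.d
        found = []
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for re0 in np.linspace(-6, 6, 31):
                for im0 in np.linspace(0.01, 1.7, 9):
                    z = re0 + 1j * im0
                    for _ in range(80):
                        e = np.exp(1j * z * d)
                        g = (1 + 1j * z * tau) * e - L
                        gp = 1j * tau * e + (1 + 1j * z * tau) * 1j * d * e
                        z = z - g / gp
                        if not np.isfinite(z):
                            break
                    if (np.isfinite(z)
                            and abs((1 + 1j * z * tau) * np.exp(1j * z * d) - L) < 1e-11
                            and abs(z.real) < 5.0 and 0 < z.imag < 1.7):
                        if not any(abs(z - f) < 1e-6 for f in found):
                            found.append(z)
        ps = poles(L, fig_kernel)
        assert len(found) >= 3
        for z in found:
            assert np.min(np.abs(ps.poles - z)) < 1e-8


class TestCrossSpectrum:
    def test_uncoupled_input_noise_is_lorentzian(self, fig_kernel, input_noise):
        om = np.linspace(-5, 5, 101)
        C = cross_spectrum(np.zeros((2, 2)), fig_kernel, input_noise, om)
        expected = 1.0 / (1.0 + om**2 * fig_kernel.tau**2)
        assert np.allclose(C[:, 0, 0].real, expected, atol=1e-12)
        assert np.allclose(C[:, 0, 1], 0.0)

    def test_uncoupled_output_noise_is_flat(self, fig_kernel, output_noise):
        om = np.linspace(-5, 5, 101)
        C = cross_spectrum(np.zeros((2, 2)), fig_kernel, output_noise, om)
        assert np.allclose(C[:, 0, 0].real, 1.0, atol=1e-12)

    def test_output_equals_input_times_inverse_kernels(self, fig_kernel, reduced_net):
        om = np.linspace(-8, 8, 201)
        Ci = cross_spectrum(reduced_net, fig_kernel, NoisePlacement("input"), om)
        Co = cross_spectrum(reduced_net, fig_kernel, NoisePlacement("output"), om)
        fac = (1.0 + om**2 * fig_kernel.tau**2)[:, None, None]
        assert np.allclose(Co, Ci * fac, rtol=1e-10)

    def test_lag_reversal_symmetry_in_frequency_domain(self, fig_kernel, reduced_net):
        # c(-t) = c(t)^T translates to C(-w) = C(w)^T
        om = np.linspace(-8, 8, 41)
        C = cross_spectrum(reduced_net, fig_kernel, NoisePlacement("output"), om)
        Cm = cross_spectrum(reduced_net, fig_kernel, NoisePlacement("output"), -om)
        assert np.allclose(Cm, np.swapaxes(C, 1, 2), atol=1e-13)
        # real covariance: C(-w) = conj(C(w))
        assert np.allclose(Cm, np.conj(C), atol=1e-13)

    def test_singular_system_raises(self):
        kern = ExponentialKernel(10.0, 0.0)
        with pytest.raises(RuntimeError, match="bifurcation"):
            cross_spectrum(np.array([[1.0]]), kern, NoisePlacement("input"),
                           np.array([0.0]))


class TestTimeDomain:
    def test_echo_function_vanishes_before_delay(self, fig_kernel):
        t = np.linspace(0, 20, 201)
        phis = phi_functions(-1.72, fig_kernel, t)
        assert np.all(phis.phi0[t < fig_kernel.d] == 0.0)
        assert np.any(phis.phi0[t > fig_kernel.d] != 0.0)

    def test_uncoupled_limit_is_exponential(self, fig_kernel):
        t = np.linspace(0, 50, 51)
        phis = phi_functions(0.0, fig_kernel, t)
        assert np.allclose(phis.phi1, np.exp(-t / 10.0) / 20.0, atol=1e-12)

    def test_residue_sums_match_quadrature(self, fig_kernel, reduced_net):
        t = np.arange(-50, 50.001, 0.5)
        om = np.linspace(-60, 60, 300001)
        for placement in ("input", "output"):
            noise = NoisePlacement(placement)
            cth = covariance_time_domain(reduced_net, fig_kernel, noise, t)
            spec = cross_spectrum(reduced_net, fig_kernel, noise, om)
            const = reduced_net.D_bar if placement == "output" else None
            cq = numeric_inverse_ft(om, spec, t, constant_part=const)
            mask = np.abs(np.abs(t) - fig_kernel.d) > 1.2
            rel = (np.linalg.norm(cth.blocks[mask] - cq.blocks[mask])
                   / np.linalg.norm(cq.blocks[mask]))
            assert rel < 0.01

    def test_symmetry_under_lag_reversal(self, fig_kernel, reduced_net):
        t = np.arange(-40, 40.001, 0.5)
        for placement in ("input", "output"):
            c = covariance_time_domain(reduced_net, fig_kernel,
                                       NoisePlacement(placement), t)
            assert c.symmetry_error() < 1e-12

    def test_output_blocks_equal_inside_delay(self, fig_kernel, reduced_net):
        t = np.arange(-40, 40.001, 0.25)
        c = covariance_time_domain(reduced_net, fig_kernel, NoisePlacement("output"), t)
        m = (np.abs(t) > 0) & (np.abs(t) < fig_kernel.d - 1e-9)
        spread = np.abs(c.blocks[m] - c.blocks[m][:, :1, :1])
        assert spread.max() < 1e-14
        # discontinuity at t = d in the echo-carrying e<-i entry: the step
        # across the delay dwarfs the smooth change one grid step earlier
        ei = c.block(0, 1)
        k = np.argmin(np.abs(t - fig_kernel.d))
        jump = abs(ei[k] - ei[k - 1])
        smooth = abs(ei[k - 1] - ei[k - 2])
        assert jump > 3 * smooth

    def test_input_solution_continuous_at_delay(self, fig_kernel, reduced_net):
        dt = 0.01
        t = np.arange(0, 10, dt)
        c = covariance_time_domain(reduced_net, fig_kernel, NoisePlacement("input"), t)
        steps = np.abs(np.diff(c.blocks, axis=0)).max(axis=(1, 2))
        k_d = np.argmin(np.abs(t - fig_kernel.d))
        assert steps[k_d - 1] < 5 * np.median(steps)
        assert steps[k_d] < 5 * np.median(steps)

    def test_uncoupled_reduced_solutions(self, fig_kernel):
        net = ReducedNetwork(M=np.zeros((2, 2)), D_bar=np.diag([0.01, 0.04]),
                             L=0.0, K=0, N_e=100, N_i=25)
        t = np.arange(-30, 30.001, 0.5)
        ci = covariance_time_domain(net, fig_kernel, NoisePlacement("input"), t)
        expected = single_unit_autocovariance(0.01, 10.0, t)
        assert np.allclose(ci.block(0, 0), expected, atol=1e-12)
        assert np.allclose(ci.block(0, 1), 0.0)
        co = covariance_time_domain(net, fig_kernel, NoisePlacement("output"), t)
        assert np.allclose(co.blocks, 0.0)
        assert np.allclose(co.delta_weight, net.D_bar)

    def test_unstable_dynamics_raises(self):
        kern = ExponentialKernel(10.0, 10.0)
        with pytest.raises(RuntimeError, match="unstable"):
            phi_functions(-2.5, kern, np.linspace(0, 10, 11))

    def test_branch_cutoff_convergence(self, fig_kernel, reduced_net):
        t = np.arange(0, 50.001, 0.5)
        mask = np.abs(t - fig_kernel.d) > 1.0
        for placement in ("input", "output"):
            noise = NoisePlacement(placement)
            c1 = covariance_time_domain(reduced_net, fig_kernel, noise, t, k_max=20)
            c2 = covariance_time_domain(reduced_net, fig_kernel, noise, t, k_max=40)
            rel = (np.linalg.norm(c1.blocks[mask] - c2.blocks[mask])
                   / np.linalg.norm(c2.blocks[mask]))
            assert rel < 1e-3


class TestDecomposition:
    @pytest.mark.parametrize("placement", ["input", "output"])
    def test_parts_sum_to_full(self, fig_kernel, reduced_net, placement):
        t = np.arange(-40, 40.001, 0.5)
        noise = NoisePlacement(placement)
        full = covariance_time_domain(reduced_net, fig_kernel, noise, t)
        parts = decompose_covariance(reduced_net, fig_kernel, noise, t)
        total = sum(p.blocks for p in parts.values())
        assert np.allclose(total, full.blocks, atol=1e-10)

    def test_output_echo_vanishes_inside_delay(self, fig_kernel, reduced_net):
        t = np.arange(-40, 40.001, 0.5)
        parts = decompose_covariance(reduced_net, fig_kernel, NoisePlacement("output"), t)
        m = np.abs(t) < fig_kernel.d - 1e-9
        assert np.abs(parts["echo_term"].blocks[m]).max() == 0.0

    def test_common_input_part_symmetric(self, fig_kernel, reduced_net):
        t = np.arange(-40, 40.001, 0.5)
        for placement in ("input", "output"):
            parts = decompose_covariance(reduced_net, fig_kernel,
                                         NoisePlacement(placement), t)
            com = parts["common_input_term"]
            assert com.symmetry_error() < 1e-12
            k = np.argmin(np.abs(t - 7.0))
            j = np.argmin(np.abs(t + 7.0))
            assert np.allclose(com.blocks[k], com.blocks[j].T, atol=1e-13)


class TestNumericInverseFT:
    def test_lorentzian_pair(self):
        tau = 8.0
        om = np.linspace(-80, 80, 200001)
        spec = 1.0 / (1.0 + om**2 * tau**2)
        t = np.linspace(-20, 20, 81)
        c = numeric_inverse_ft(om, spec, t)
        assert np.allclose(c.blocks[:, 0, 0], np.exp(-np.abs(t) / tau) / (2 * tau),
                           atol=1e-4)

    def test_flat_spectrum_requires_declared_constant(self):
        om = np.linspace(-10, 10, 1001)
        spec = np.ones_like(om)
        with pytest.raises(ValueError, match="constant part"):
            numeric_inverse_ft(om, spec, np.linspace(-5, 5, 11))
        c = numeric_inverse_ft(om, spec, np.linspace(-5, 5, 11),
                               constant_part=np.array([[1.0]]))
        assert np.allclose(c.blocks, 0.0, atol=1e-12)
        assert np.allclose(c.delta_weight, 1.0)
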