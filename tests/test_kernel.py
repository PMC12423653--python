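"""Swimming-speed kernel: structure, bilinear speeds, shapes and the speed oracle.

The central correctness property of the package is the equivalence of the
two independent routes to the reduced swimming speed: the kernel double
quadrature and the time-averaged shape motion.
"""

import numpy as np
import pytest

from actifil.exceptions import InvalidParameterError
from actifil.kernel import (
    compute_kernels,
    filament_shape,
    speed_quadrature,
    speed_time_average_oracle,
)
from actifil.modal import travelling_wave_kernel
from actifil.profiles import ForcingProfile, fixture_profiles


class TestKernelStructure:
    def test_parity_structure(self, kernel47):
        gs, ga, gw = kernel47.gs_matrix, kernel47.ga_matrix, kernel47.gswim_matrix
        assert np.max(np.abs(gs - gs.T)) < 1e-12
        assert np.max(np.abs(ga + ga.T)) < 1e-12
        assert np.max(np.abs(gw - gw.T)) < 1e-12

    def test_monophasic_kernel_equals_symmetric_part(self, kernel47):
        assert np.array_equal(kernel47.gswim_matrix, kernel47.gs_matrix)

    def test_travelling_wave_assembly(self, kernel_wave):
        nodes = kernel_wave.nodes
        dphi = 2 * np.pi * 0.72 * (nodes[:, None] - nodes[None, :])
        expected = kernel_wave.gs_matrix * np.cos(dphi) + kernel_wave.ga_matrix * np.sin(dphi)
        expected = 0.5 * (expected + expected.T)
        assert np.max(np.abs(kernel_wave.gswim_matrix - expected)) < 1e-14
        assert np.max(np.abs(kernel_wave.gswim_matrix - kernel_wave.gswim_matrix.T)) < 1e-12

    def test_minimum_node_count(self):
        with pytest.raises(InvalidParameterError):
            compute_kernels(4.7, n=5)


class TestSpeedQuadrature:
    def test_scallop_theorem_uniform_monophasic(self, kernel47):
        u = speed_quadrature(kernel47, fixture_profiles("constant"))
        assert abs(u) < 1e-10

    def test_bilinearity(self, kernel47):
        f = fixture_profiles("random", seed=7)
        u1 = speed_quadrature(kernel47, f)
        f2 = ForcingProfile.from_function(lambda x, _f=f.f: 2.0 * _f(x))
        assert speed_quadrature(kernel47, f2) == pytest.approx(4.0 * u1, rel=1e-13)

    def test_bilinear_expansion(self, kernel47):
        fa = fixture_profiles("random", seed=11)
        fb = fixture_profiles("random", seed=13)
        a, b = 0.7, -1.3
        mix = ForcingProfile.from_function(
            lambda x, _fa=fa.f, _fb=fb.f: a * _fa(x) + b * _fb(x)
        )
        va = fa.magnitude(kernel47.nodes)
        vb = fb.magnitude(kernel47.nodes)
        cross = float(va @ kernel47.gswim_matrix @ vb) / kernel47.n**2
        expected = (
            a**2 * speed_quadrature(kernel47, fa)
            + 2 * a * b * cross
            + b**2 * speed_quadrature(kernel47, fb)
        )
        assert speed_quadrature(kernel47, mix) == pytest.approx(expected, rel=1e-12)

    def test_reflection_antisymmetry_monophasic(self, kernel47, random_profiles):
        for prof in random_profiles:
            mirrored = ForcingProfile.from_function(lambda x, _f=prof.f: _f(1.0 - np.asarray(x)))
            u = speed_quadrature(kernel47, prof)
            u_m = speed_quadrature(kernel47, mirrored)
            assert u_m == pytest.approx(-u, rel=1e-10, abs=1e-18)

    def test_discrete_actuators_use_exact_kernel(self, kernel47):
        prof = ForcingProfile.from_actuators([(0.309, 1.0)])
        u = speed_quadrature(kernel47, prof)
        expected = float(kernel47.kernel_value([0.309], [0.309])[0, 0])
        assert u == pytest.approx(expected, rel=1e-14)

    def test_single_actuator_speed_factor(self, kernel47, system47):
        # point forcing at 0.309 reaches ~2.8x the dominant-eigenvalue speed
        prof = ForcingProfile.from_actuators([(0.309, 1.0)])
        u = speed_quadrature(kernel47, prof)
        assert u / system47.lambda_plus == pytest.approx(2.804, rel=0.01)


class TestFilamentShape:
    def test_zero_forcing_is_straight(self):
        prof = ForcingProfile.from_function(lambda x: np.zeros_like(np.asarray(x, float)))
        shape = filament_shape(4.7, prof, np.linspace(0, 1, 41),
                               np.linspace(0, 2 * np.pi, 64, endpoint=False))
        assert np.max(np.abs(shape.y)) == 0.0
        assert np.max(np.abs(shape.tip_velocity)) == 0.0

    @pytest.mark.parametrize("profile", [
        fixture_profiles("constant"),
        fixture_profiles("piecewise", breaks=[0.625], values=[1.0, 0.0]),
        fixture_profiles("actuators", actuators=[(0.309, 1.0)]),
        fixture_profiles("constant", k=1.5),
    ], ids=["uniform", "front", "actuator", "wave"])
    def test_global_torque_vanishes(self, profile, uniform_time_grid):
        shape = filament_shape(4.0, profile, np.linspace(0, 1, 101), uniform_time_grid)
        assert np.max(np.abs(shape.torque)) < 1e-8 * np.max(np.abs(shape.y))

    def test_tip_velocity_averages_to_zero(self, uniform_time_grid):
        shape = filament_shape(4.7, fixture_profiles("random", seed=3),
                               np.linspace(0, 1, 41), uniform_time_grid)
        assert abs(np.mean(shape.tip_velocity)) < 1e-8 * np.max(np.abs(shape.tip_velocity))

    def test_fields_are_derivative_chain(self, uniform_time_grid):
        prof = fixture_profiles("random", seed=5)
        shape = filament_shape(4.7, prof, np.linspace(0, 1, 41), uniform_time_grid)
        eit = np.exp(1j * shape.t_grid)[:, None]
        assert np.allclose(shape.y, np.real(eit * shape.psi_cap[2][None, :]))
        assert np.allclose(shape.tangent_angle, np.real(eit * shape.psi_cap[3][None, :]))

    def test_short_time_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            filament_shape(4.7, fixture_profiles("constant"),
                           np.linspace(0, 1, 11), np.linspace(0, np.pi, 32))


class TestSpeedOracle:
    def test_zero_for_uniform_monophasic(self, uniform_time_grid):
        shape = filament_shape(4.7, fixture_profiles("constant"),
                               np.linspace(0, 1, 801), uniform_time_grid)
        assert abs(speed_time_average_oracle(shape)) < 1e-8

    @pytest.mark.parametrize("sp", [2.0, 4.7])
    def test_oracle_equivalence_random_profiles(self, sp, random_profiles, uniform_time_grid):
        """Kernel double quadrature vs time-averaged shape motion (< 1e-4).

        N = 200 midpoint nodes: the kernel route converges at second order in
        1/N and needs that resolution to push its discretization error below
        the comparison tolerance for profiles with strong cancellation.
        """
        kernel = compute_kernels(sp, n=200)
        s_grid = np.linspace(0, 1, 801)
        for prof in random_profiles:
            u_kernel = speed_quadrature(kernel, prof)
            shape = filament_shape(sp, prof, s_grid, uniform_time_grid)
            u_oracle = speed_time_average_oracle(shape)
            assert u_kernel == pytest.approx(u_oracle, rel=1e-4)

    def test_oracle_equivalence_travelling_wave(self, uniform_time_grid):
        kernel = travelling_wave_kernel(3.0, 0.72, n=200)
        prof = fixture_profiles("constant", k=0.72)
        u_kernel = speed_quadrature(kernel, prof)
        shape = filament_shape(3.0, prof, np.linspace(0, 1, 801), uniform_time_grid)
        assert u_kernel == pytest.approx(speed_time_average_oracle(shape), rel=1e-4)

    def test_insufficient_time_samples_rejected(self, uniform_time_grid):
        shape = filament_shape(4.7, fixture_profiles("constant"),
                               np.linspace(0, 1, 101), uniform_time_grid)
        object.__setattr__(shape, "t_grid", shape.t_grid[:32])
        with pytest.raises(InvalidParameterError):
            speed_time_average_oracle(shape)
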