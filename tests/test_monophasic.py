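"""Analytic monophasic eigensystem: mode pairs, eigenvalues and speed formulas."""

import numpy as np
import pytest

from actifil.exceptions import InvalidParameterError
from actifil.kernel import compute_kernels, speed_quadrature
from actifil.monophasic import analytic_system, lambda_curves, natural_pair, speed_monophasic
from actifil.profiles import ForcingProfile, fixture_profiles


class TestNaturalPair:
    def test_parity(self):
        fs, fa = natural_pair(4.7)
        for d in (0.1, 0.3):
            assert abs(fs(0.5 + d) - fs(0.5 - d)) < 1e-10 * abs(fs(0.5 + d))
            assert abs(fa(0.5 + d) + fa(0.5 - d)) < 1e-10 * abs(fa(0.5 + d))
        assert abs(fa(0.5)) < 1e-12

    def test_vanish_at_ends(self):
        fs, fa = natural_pair(3.0)
        for f in (fs, fa):
            assert abs(f(0.0)) < 1e-12
            assert abs(f(1.0)) < 1e-12

    @pytest.mark.parametrize("which", [0, 1], ids=["fs", "fa"])
    def test_satisfies_natural_mode_equation(self, which):
        # exact differentiation of the exponential-polynomial representation
        f = natural_pair(4.7)[which]
        f4 = f.deriv().deriv().deriv().deriv()
        xi = np.linspace(0.1, 0.9, 9)
        residual = 4.7**4 * 1j * f(xi) + f4(xi)
        assert np.max(np.abs(residual)) < 1e-9 * np.max(np.abs(f4(xi)))

    def test_numerical_fourth_derivative_residual(self):
        # independent check through a 5-point stencil with h = 1e-3
        fs, _ = natural_pair(4.7)
        h = 1e-3
        stencil = np.array([1.0, -4.0, 6.0, -4.0, 1.0])
        xi = np.array([0.3, 0.6])
        f4 = np.array([np.sum(stencil * fs(x + np.arange(-2, 3) * h)) / h**4 for x in xi])
        residual = 4.7**4 * 1j * fs(xi) + f4
        assert np.max(np.abs(residual)) < 1e-4 * np.max(np.abs(f4))

    def test_out_of_range_sperm_number(self):
        with pytest.raises(InvalidParameterError):
            natural_pair(-1.0)


class TestEigenSystem:
    def test_dominant_eigenvalue_at_reference_sperm_number(self, system47):
        assert system47.lambda_plus == pytest.approx(0.00170, rel=0.02)

    def test_eigenvalue_hierarchy(self, system47):
        ratio = system47.lambda_plus / system47.lambda_minus
        assert 100 * 0.8 <= ratio <= 100 * 1.2

    def test_matches_numeric_eigendecomposition(self, system47, basis47):
        assert system47.lambda_plus == pytest.approx(basis47.eigenvalues[0], rel=1e-5)
        assert system47.lambda_minus == pytest.approx(basis47.eigenvalues[2], rel=1e-5)

    def test_matrix_spectrum_is_plus_minus_pairs(self, system47):
        evals = np.sort(np.linalg.eigvals(system47.matrix4).real)
        expected = np.sort([
            system47.lambda_plus, system47.lambda_minus,
            -system47.lambda_minus, -system47.lambda_plus,
        ])
        assert np.allclose(evals, expected, rtol=1e-10, atol=1e-18)

    def test_reflection_symmetry_of_coefficients(self, system47):
        # flipping the antisymmetric coefficients negates the eigenvalue
        af, bf, cf, df = system47.gplus_coeffs
        flipped = np.array([af, -bf, cf, -df])
        out = system47.matrix4 @ flipped
        assert np.allclose(out, -system47.lambda_plus * flipped, rtol=1e-8)

    def test_gs_ga_parity(self, system47):
        s = np.linspace(0.0, 1.0, 101)
        assert np.max(np.abs(system47.gs(s) - system47.gs(1 - s))) < 1e-10
        assert np.max(np.abs(system47.ga(s) + system47.ga(1 - s))) < 1e-10

    def test_eigenfunctions_unit_mean_square(self, system47):
        for poly in (system47.gplus_poly, system47.gminus_poly):
            norm2 = np.real((poly * poly).integral(0.0, 1.0))
            assert norm2 == pytest.approx(1.0, rel=1e-10)

    def test_eigenfunction_orthogonal_to_its_reflection(self, system47):
        overlap = np.real((system47.gplus_poly * system47.gplus_poly.reflect()).integral(0, 1))
        assert abs(overlap) < 1e-8


@pytest.fixture(scope="module")
def curves():
    return lambda_curves(np.arange(4.0, 5.5, 0.01))


class TestLambdaCurves:
    def test_single_interior_maximum_near_reference(self, curves):
        sp_star = curves.loc[curves["lambda_plus"].idxmax(), "sp"]
        assert sp_star == pytest.approx(4.70, abs=0.05)

    def test_curves_positive(self, curves):
        assert (curves["lambda_plus"] > 0).all()
        assert (curves["lambda_minus"] > 0).all()

    def test_max_ratio_about_twenty(self):
        sweep = lambda_curves(np.arange(0.5, 10.01, 0.05))
        ratio = sweep["lambda_plus"].max() / sweep["lambda_minus"].max()
        assert 20 * 0.8 <= ratio <= 20 * 1.2


class TestSpeedFormulas:
    @pytest.mark.parametrize("method", ["four_mode", "dominant", "diff_of_squares"])
    def test_uniform_forcing_cannot_swim(self, system47, method):
        u = speed_monophasic(system47, fixture_profiles("constant"), method=method)
        assert abs(u) < 1e-12

    def test_optimal_single_actuator_speed(self, system47):
        prof = ForcingProfile.from_actuators([(0.309, 1.0)])
        u = speed_monophasic(system47, prof, method="four_mode")
        assert u / system47.lambda_plus == pytest.approx(2.804, rel=0.01)

    def test_unit_l1_eigenfunction_speed(self, system47):
        # integral of |g+| via dense sampling
        xi = np.linspace(0, 1, 20001)
        l1 = np.trapezoid(np.abs(system47.gplus(xi)), xi)
        prof = ForcingProfile.from_function(
            lambda x, _s=system47, _l1=l1: _s.gplus(x) / _l1
        )
        u = speed_monophasic(system47, prof, method="four_mode")
        assert u / system47.lambda_plus == pytest.approx(1.420, rel=0.01)

    def test_diff_of_squares_equals_dominant(self, system47, random_profiles):
        for prof in random_profiles:
            u1 = speed_monophasic(system47, prof, method="dominant")
            u2 = speed_monophasic(system47, prof, method="diff_of_squares")
            assert u2 == pytest.approx(u1, rel=1e-10, abs=1e-20)

    @pytest.mark.parametrize("method", ["four_mode", "dominant", "diff_of_squares"])
    def test_reflection_negates_speed(self, system47, method, random_profiles):
        prof = random_profiles[0]
        mirrored = ForcingProfile.from_function(lambda x, _f=prof.f: _f(1.0 - np.asarray(x)))
        u = speed_monophasic(system47, prof, method=method)
        u_m = speed_monophasic(system47, mirrored, method=method)
        assert u_m == pytest.approx(-u, rel=1e-10, abs=1e-20)

    def test_dominant_close_to_four_mode(self, system47):
        # the lambda- pair contributes at most ~ lambda-/lambda+ relatively
        for prof in (
            ForcingProfile.from_actuators([(0.309, 1.0)]),
            fixture_profiles("piecewise", breaks=[0.701], values=[1.0, -1.0]),
        ):
            u4 = speed_monophasic(system47, prof, method="four_mode")
            u1 = speed_monophasic(system47, prof, method="dominant")
            assert abs(u4 - u1) / abs(u4) < 2 * system47.lambda_minus / system47.lambda_plus

    def test_four_mode_consistent_with_kernel_quadrature(self, system47, random_profiles):
        """Analytic four-mode speed vs Richardson-extrapolated midpoint speed.

        The midpoint double quadrature converges at O(1/N^2); extrapolating
        the N=100 and N=400 values removes that discretization error and the
        two routes then agree far inside 1e-5 relative.
        """
        k100 = compute_kernels(4.7, n=100)
        k400 = compute_kernels(4.7, n=400)
        for prof in random_profiles:
            u_analytic = speed_monophasic(system47, prof, method="four_mode")
            u_extrap = (16 * speed_quadrature(k400, prof) - speed_quadrature(k100, prof)) / 15
            assert u_analytic == pytest.approx(u_extrap, rel=1e-5)

    def test_phase_bearing_profile_rejected(self, system47):
        with pytest.raises(InvalidParameterError):
            speed_monophasic(system47, fixture_profiles("constant", k=0.72))
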