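"""Analytic eigensystem of the monophasic (phase-free) swimming-speed kernel.

When the internal moment forcing is entirely in phase (phi = 0, the regime of
magnetically or muscle-actuated artificial swimmers), the swimming-speed
operator has exactly four non-zero eigenvalues.  An eigenfunction ``f`` with
non-zero eigenvalue must satisfy ``lambda f = Re[I3]`` where

    Sp^4 i I1 + I1'''' = f,     Sp^4 i I2 + I2'''' = f',
    I3 = (I1' - I2) / (2i),     I(0) = I(1) = I'(0) = I'(1) = 0,

and I3 solves the homogeneous natural-mode equation with I3(0) = I3(1) = 0.
This forces ``f`` to be a real combination of the four functions
``Re[fs], Re[fa], Re[i fs], Re[i fa]`` built from the symmetric and
antisymmetric natural-mode pairs (denominators ``1 +- e^{Sp eta}`` and
``1 +- e^{Sp eta i}``, with ``eta = e^{-i pi/8}``).  Solving the four
boundary-coefficient systems and collecting the natural-mode content of I3
yields a real 4x4 eigenproblem whose spectrum is ``{l+, l-, -l-, -l+}``; the
positive pair ``lambda_plus >= lambda_minus`` and their eigenfunctions
``g+, g-`` govern monophasic swimming entirely.  All function algebra is done
exactly on exponential polynomials, so the eigenfunction integrals used by
the optimizers have no quadrature error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConditioningError, InvalidParameterError
from .exppoly import ExpPoly
from .greens import ETA, MODE_UNITS, _gauss_panel
from .profiles import ForcingProfile

__all__ = [
    "AnalyticEigenSystem",
    "natural_pair",
    "analytic_system",
    "lambda_curves",
    "speed_monophasic",
]

_SP_MAX = 30.0
_COND_LIMIT = 1e12


def _natural_wavenumbers(sp: float) -> np.ndarray:
    return (sp * ETA) * MODE_UNITS


def natural_pair(sp: float) -> tuple[ExpPoly, ExpPoly]:
    """The symmetric/antisymmetric natural-mode combinations (fs, fa).

    fs(1 - xi) = fs(xi), fa(1 - xi) = -fa(xi), fs(0) = fs(1) = fa(0) = fa(1) = 0,
    and both satisfy the homogeneous equation Sp^4 i F + F'''' = 0.
    """
    sp = float(sp)
    if not np.isfinite(sp) or sp <= 0.0 or sp > _SP_MAX:
        raise InvalidParameterError(f"sperm number must lie in (0, {_SP_MAX}], got {sp}")
    ka = sp * ETA
    kb = sp * ETA * 1j
    ea, eb = np.exp(ka), np.exp(kb)
    for name, den in (("1+e^(Sp eta)", 1 + ea), ("1-e^(Sp eta)", 1 - ea),
                      ("1+e^(Sp eta i)", 1 + eb), ("1-e^(Sp eta i)", 1 - eb)):
        if abs(den) < 1e-12:
            raise InvalidParameterError(f"degenerate denominator {name} at sp={sp}")
    fs = ExpPoly({
        (ka, 0): 1.0 / (1 + ea), (-ka, 0): ea / (1 + ea),
        (kb, 0): -1.0 / (1 + eb), (-kb, 0): -eb / (1 + eb),
    })
    fa = ExpPoly({
        (ka, 0): 1.0 / (1 - ea), (-ka, 0): -ea / (1 - ea),
        (kb, 0): -1.0 / (1 - eb), (-kb, 0): eb / (1 - eb),
    })
    return fs, fa


def _solve_forced_mode(sp: float, rhs: ExpPoly) -> ExpPoly:
    """Solve Sp^4 i I + I'''' = rhs with I = I' = 0 at both ends.

    ``rhs`` must contain only degree-0 natural modes (resonant, handled via
    xi e^{k xi} particular terms) and their complex conjugates (non-resonant).
    """
    ks = _natural_wavenumbers(sp)
    natural = set((complex(k) for k in ks))
    conjugate = set((complex(np.conj(k)) for k in ks))
    part: dict[tuple[complex, int], complex] = {}
    for (k, p), c in rhs.terms.items():
        if p != 0:
            raise InvalidParameterError("forcing term of unsupported polynomial degree")
        if k in natural:
            key = (k, 1)
            part[key] = part.get(key, 0.0) + c / (4.0 * k**3)
        elif k in conjugate:
            key = (k, 0)
            part[key] = part.get(key, 0.0) + c / (2.0 * sp**4 * 1j)
        else:
            raise InvalidParameterError("forcing contains a non-natural mode")
    particular = ExpPoly(part)
    # homogeneous basis scaled per mode: growing exponentials anchored at xi = 1
    refs = np.where(ks.real > 0.0, 1.0, 0.0)
    mat = np.zeros((4, 4), dtype=complex)
    for j, (k, r) in enumerate(zip(ks, refs)):
        mat[0, j] = np.exp(k * (0.0 - r))
        mat[1, j] = np.exp(k * (1.0 - r))
        mat[2, j] = k * np.exp(k * (0.0 - r))
        mat[3, j] = k * np.exp(k * (1.0 - r))
    dpart = particular.deriv()
    rhs_vec = -np.array([particular(0.0), particular(1.0), dpart(0.0), dpart(1.0)])
    if np.linalg.cond(mat) > _COND_LIMIT:
        raise ConditioningError(f"boundary-coefficient system ill-conditioned at sp={sp}")
    coeffs = np.linalg.solve(mat, rhs_vec)
    hom = ExpPoly({(complex(k), 0): c * np.exp(-k * r) for k, r, c in zip(ks, refs, coeffs)})
    return particular + hom


def _natural_content(sp: float, func: ExpPoly) -> dict[complex, complex]:
    """Degree-0 natural-mode coefficients; errors if anything else survives."""
    ks = [complex(k) for k in _natural_wavenumbers(sp)]
    content = {k: 0.0 + 0.0j for k in ks}
    top = func.max_abs_coeff()
    for (k, p), c in func.terms.items():
        if p == 0 and k in content:
            content[k] += c
        elif abs(c) > 1e-7 * top:
            raise ConditioningError(
                f"non-natural residual mode (k={k}, p={p}) with coefficient {abs(c):.2e} "
                f"relative {abs(c) / top:.2e} at sp={sp}"
            )
    return content


@dataclass(frozen=True)
class AnalyticEigenSystem:
    """The monophasic 4x4 eigenproblem and its positive eigenpair functions.

    ``gplus_poly``/``gminus_poly`` are real-valued exponential polynomials
    sampling the eigenfunctions g+ and g- (unit mean-square normalization,
    sign fixed so int_0^1/2 g+ > 0); ``gs_poly = g+(s) + g+(1-s)`` and
    ``ga_poly = g+(s) - g+(1-s)`` are their symmetric/antisymmetric doubles
    used by the piecewise and discrete-actuator optimizers.
    """

    sp: float
    eta: complex
    fs: ExpPoly
    fa: ExpPoly
    e3: dict
    matrix4: np.ndarray
    lambda_plus: float
    lambda_minus: float
    gplus_coeffs: np.ndarray
    gminus_coeffs: np.ndarray
    gplus_poly: ExpPoly
    gminus_poly: ExpPoly
    gs_poly: ExpPoly
    ga_poly: ExpPoly

    def gplus(self, xi):
        return self.gplus_poly.real_eval(xi)

    def gminus(self, xi):
        return self.gminus_poly.real_eval(xi)

    def gs(self, xi):
        return self.gs_poly.real_eval(xi)

    def ga(self, xi):
        return self.ga_poly.real_eval(xi)


def _real_poly(fs: ExpPoly, fa: ExpPoly, coeffs: np.ndarray) -> ExpPoly:
    """The real-valued eigenfunction Af Re[fs] + Bf Re[fa] + Cf Re[i fs] + Df Re[i fa]."""
    af, bf, cf, df = (float(c) for c in coeffs)
    z = fs.scale(af + 1j * cf) + fa.scale(bf + 1j * df)
    return z.scale(0.5) + z.conj().scale(0.5)


def _normalize(poly: ExpPoly) -> ExpPoly:
    norm2 = poly.__mul__(poly).integral(0.0, 1.0)
    norm2 = float(np.real(norm2))
    if norm2 <= 0.0:
        raise ConditioningError("eigenfunction has non-positive mean square")
    out = poly.scale(1.0 / np.sqrt(norm2))
    front = float(np.real(out.antideriv()(0.5) - out.antideriv()(0.0)))
    if front < 0.0:
        out = out.scale(-1.0)
    return out


def analytic_system(sp: float) -> AnalyticEigenSystem:
    """Assemble and solve the monophasic 4x4 eigenproblem at sperm number sp."""
    sp = float(sp)
    fs, fa = natural_pair(sp)
    e3: dict[tuple[str, str], complex] = {}
    for b_label, b in (("1", 1.0 + 0.0j), ("i", 1j)):
        for parity, fp, fother in (("s", fs, fa), ("a", fa, fs)):
            forcing = fp.scale(b / 2.0) + fp.conj().scale(np.conj(b) / 2.0)
            i1 = _solve_forced_mode(sp, forcing)
            i2 = _solve_forced_mode(sp, forcing.deriv())
            # lambda f = (1/2) Im[-I1' + I2] = Re[(I2 - I1') / 2i]; the
            # orientation (rather than the +- pair of eigenvalues) is fixed by
            # cross-checking speeds against the time-averaged shape motion
            i3 = (i2 - i1.deriv()).scale(1.0 / (2.0j))
            content = _natural_content(sp, i3)
            other = _natural_content(sp, fother)
            # I3 must be proportional to the opposite-parity pair function;
            # extract the ratio from the best-conditioned mode and verify the rest.
            ratios = {k: content[k] / other[k] for k in content if abs(other[k]) > 0.0}
            kmax = max(ratios, key=lambda k: abs(other[k]))
            val = ratios[kmax]
            spread = max(abs(r - val) for r in ratios.values())
            if spread > 1e-6 * max(abs(val), 1e-300):
                raise ConditioningError(
                    f"I3 not proportional to the opposite-parity mode pair at sp={sp} "
                    f"(spread {spread:.2e} vs {abs(val):.2e})"
                )
            e3[(b_label, parity)] = val
    m = np.array([
        [0.0, np.real(e3[("1", "a")]), 0.0, np.real(e3[("i", "a")])],
        [np.real(e3[("1", "s")]), 0.0, np.real(e3[("i", "s")]), 0.0],
        [0.0, np.imag(e3[("1", "a")]), 0.0, np.imag(e3[("i", "a")])],
        [np.imag(e3[("1", "s")]), 0.0, np.imag(e3[("i", "s")]), 0.0],
    ])
    # the matrix couples (Af, Cf) only to (Bf, Df); eigen-solving the 2x2
    # block product for lambda^2 preserves the exact +- pair structure and
    # stays robust when lambda- is many orders below lambda+
    block_a = np.array([
        [np.real(e3[("1", "a")]), np.real(e3[("i", "a")])],
        [np.imag(e3[("1", "a")]), np.imag(e3[("i", "a")])],
    ])
    block_s = np.array([
        [np.real(e3[("1", "s")]), np.real(e3[("i", "s")])],
        [np.imag(e3[("1", "s")]), np.imag(e3[("i", "s")])],
    ])
    m2 = block_s @ block_a
    tr = float(np.trace(m2))
    # det(Bs Ba) = det(Bs) det(Ba): avoids the catastrophic cancellation of
    # forming the product's determinant when lambda- << lambda+
    det = float(np.linalg.det(block_s) * np.linalg.det(block_a))
    disc = tr * tr - 4.0 * det
    if disc < -1e-12 * tr * tr or tr <= 0.0:
        raise ConditioningError(f"monophasic lambda^2 pair not real positive at sp={sp}")
    mu_plus = 0.5 * (tr + np.sqrt(max(disc, 0.0)))
    mu_minus = det / mu_plus
    # below the assembly's cancellation noise the subdominant eigenvalue is
    # indistinguishable from zero (it only enters speeds multiplied by
    # itself); clamp rather than fail, keeping the sweep over Sp usable
    noise_floor = 1e-12 * mu_plus
    mu_minus_eff = max(mu_minus, noise_floor)
    evals = [float(np.sqrt(mu_plus)), float(np.sqrt(max(mu_minus, 0.0)))]

    def _bd_vector(mu):
        cands = (np.array([m2[0, 1], mu - m2[0, 0]]), np.array([mu - m2[1, 1], m2[1, 0]]))
        bd = max(cands, key=lambda v: float(np.linalg.norm(v)))
        return bd / np.linalg.norm(bd)

    evecs = []
    for mu, lam_sq in ((mu_plus, mu_plus), (mu_minus, mu_minus_eff)):
        bd = _bd_vector(mu)
        ac = block_a @ bd / np.sqrt(lam_sq)
        evecs.append(np.array([ac[0], bd[0], ac[1], bd[1]]))
    i_plus, i_minus = 0, 1
    gplus_poly = _normalize(_real_poly(fs, fa, evecs[i_plus]))
    gminus_poly = _normalize(_real_poly(fs, fa, evecs[i_minus]))
    gs_poly = gplus_poly + gplus_poly.reflect()
    ga_poly = gplus_poly - gplus_poly.reflect()
    return AnalyticEigenSystem(
        sp=sp, eta=ETA, fs=fs, fa=fa, e3=e3, matrix4=m,
        lambda_plus=float(evals[i_plus]), lambda_minus=float(evals[i_minus]),
        gplus_coeffs=evecs[i_plus], gminus_coeffs=evecs[i_minus],
        gplus_poly=gplus_poly, gminus_poly=gminus_poly,
        gs_poly=gs_poly, ga_poly=ga_poly,
    )


def lambda_curves(sp_grid) -> pd.DataFrame:
    """Tabulate the analytic positive eigenvalues lambda_plus/minus over Sp."""
    sp_grid = np.atleast_1d(np.asarray(sp_grid, dtype=float))
    rows = []
    for sp in sp_grid:
        system = analytic_system(sp)
        rows.append((sp, system.lambda_plus, system.lambda_minus))
    return pd.DataFrame(rows, columns=["sp", "lambda_plus", "lambda_minus"])


def _profile_integral(forcing: ForcingProfile, poly: ExpPoly) -> float:
    """int f(xi) g(xi) dxi for a continuous profile against a mode function.

    Piecewise-constant profiles (those carrying ``segments``) integrate
    exactly through the mode antiderivative; smooth profiles use composite
    Gauss-Legendre panels.
    """
    if forcing.segments is not None:
        edges, values = forcing.segments
        anti = poly.antideriv()
        vals = anti(np.asarray(edges, dtype=float))
        return float(np.real(np.sum(np.asarray(values) * np.diff(vals))))
    panels = np.linspace(0.0, 1.0, 21)
    nodes, weights = _gauss_panel(panels[:-1], panels[1:], 20)
    return float(np.sum(weights * forcing.magnitude(nodes) * poly.real_eval(nodes)))


def speed_monophasic(system: AnalyticEigenSystem, forcing: ForcingProfile, method: str = "four_mode") -> float:
    """Reduced speed of a monophasic profile from the analytic eigenpair.

    ``four_mode`` uses both positive eigenpairs and their reflections (exact);
    ``dominant`` drops the lambda_minus pair; ``diff_of_squares`` is the
    dominant-mode speed written as lambda_plus [int f gs][int f ga], an exact
    algebraic rewriting of ``dominant``.
    """
    if not forcing.is_monophasic:
        raise InvalidParameterError("analytic monophasic formulas require phase identically zero")
    if method not in ("four_mode", "dominant", "diff_of_squares"):
        raise InvalidParameterError(f"unknown method {method!r}")

    if forcing.kind == "discrete":
        locs, strengths = forcing.actuator_arrays()

        def pair(poly):
            a = float(np.sum(strengths * poly.real_eval(locs)))
            b = float(np.sum(strengths * poly.real_eval(1.0 - locs)))
            return a, b

    else:

        def pair(poly):
            a = _profile_integral(forcing, poly)
            b = _profile_integral(forcing, poly.reflect())
            return a, b

    if method == "diff_of_squares":
        s_int = _sum_against(system.gs_poly, forcing)
        a_int = _sum_against(system.ga_poly, forcing)
        return float(system.lambda_plus * s_int * a_int)

    a_p, b_p = pair(system.gplus_poly)
    u = system.lambda_plus * (a_p**2 - b_p**2)
    if method == "four_mode":
        a_m, b_m = pair(system.gminus_poly)
        u += system.lambda_minus * (a_m**2 - b_m**2)
    return float(u)


def _sum_against(poly: ExpPoly, forcing: ForcingProfile) -> float:
    if forcing.kind == "discrete":
        locs, strengths = forcing.actuator_arrays()
        return float(np.sum(strengths * poly.real_eval(locs)))
    return _profile_integral(forcing, poly)
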