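"""Exact algebra on exponential polynomials sum c xi^p e^{k xi}.

The analytic monophasic eigenproblem manipulates functions built entirely
from the filament's natural modes ``e^{k xi}`` (with ``k^4 = -Sp^4 i``),
their complex conjugates, and resonance terms ``xi e^{k xi}``.  Representing
them as sparse term dictionaries keyed by ``(k, p)`` lets differentiation,
antidifferentiation, products and reflections be carried out exactly, so the
eigenfunction integrals needed by the swimmer optimizers incur no quadrature
error.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ExpPoly"]


class ExpPoly:
    """A finite sum of terms ``c * xi**p * exp(k * xi)`` (c, k complex; p >= 0)."""

    __slots__ = ("terms",)

    def __init__(self, terms=None):
        self.terms: dict[tuple[complex, int], complex] = {}
        if terms:
            for (k, p), c in dict(terms).items():
                if c != 0:
                    self.terms[(complex(k), int(p))] = complex(c)

    # ------------------------------------------------------------------ algebra

    def __add__(self, other: "ExpPoly") -> "ExpPoly":
        out = dict(self.terms)
        for key, c in other.terms.items():
            out[key] = out.get(key, 0.0) + c
        return ExpPoly(out)

    def __sub__(self, other: "ExpPoly") -> "ExpPoly":
        return self + other.scale(-1.0)

    def scale(self, factor: complex) -> "ExpPoly":
        return ExpPoly({key: c * factor for key, c in self.terms.items()})

    def __mul__(self, other: "ExpPoly") -> "ExpPoly":
        out: dict[tuple[complex, int], complex] = {}
        for (k1, p1), c1 in self.terms.items():
            for (k2, p2), c2 in other.terms.items():
                key = (k1 + k2, p1 + p2)
                out[key] = out.get(key, 0.0) + c1 * c2
        return ExpPoly(out)

    def conj(self) -> "ExpPoly":
        return ExpPoly({(np.conj(k), p): np.conj(c) for (k, p), c in self.terms.items()})

    def reflect(self) -> "ExpPoly":
        """The function xi -> self(1 - xi); requires polynomial degree <= 1."""
        out: dict[tuple[complex, int], complex] = {}
        for (k, p), c in self.terms.items():
            if p == 0:
                key = (-k, 0)
                out[key] = out.get(key, 0.0) + c * np.exp(k)
            elif p == 1:
                # c (1 - xi) e^{k(1-xi)} = c e^k e^{-k xi} - c e^k xi e^{-k xi}
                for key, cc in (((-k, 0), c * np.exp(k)), ((-k, 1), -c * np.exp(k))):
                    out[key] = out.get(key, 0.0) + cc
            else:
                raise NotImplementedError("reflection implemented for degree <= 1 terms")
        return ExpPoly(out)

    # ------------------------------------------------------------------ calculus

    def deriv(self) -> "ExpPoly":
        out: dict[tuple[complex, int], complex] = {}
        for (k, p), c in self.terms.items():
            if k != 0:
                key = (k, p)
                out[key] = out.get(key, 0.0) + c * k
            if p > 0:
                key = (k, p - 1)
                out[key] = out.get(key, 0.0) + c * p
        return ExpPoly(out)

    def antideriv(self) -> "ExpPoly":
        out = ExpPoly()
        for (k, p), c in self.terms.items():
            out = out + _term_antideriv(k, p, c)
        return out

    def integral(self, a: float = 0.0, b: float = 1.0) -> complex:
        anti = self.antideriv()
        return anti(b) - anti(a)

    # ------------------------------------------------------------------ evaluation

    def __call__(self, xi):
        xi = np.asarray(xi, dtype=float)
        out = np.zeros(xi.shape, dtype=complex)
        for (k, p), c in self.terms.items():
            term = c * np.exp(k * xi)
            if p:
                term = term * xi**p
            out = out + term
        return out if out.shape else complex(out)

    def real_eval(self, xi):
        """Real part of the value; for real-valued combinations this is the value."""
        val = self(xi)
        return np.real(val)

    # ------------------------------------------------------------------ misc

    def max_abs_coeff(self) -> float:
        return max((abs(c) for c in self.terms.values()), default=0.0)

    def prune(self, rel_tol: float) -> "ExpPoly":
        top = self.max_abs_coeff()
        return ExpPoly({key: c for key, c in self.terms.items() if abs(c) > rel_tol * top})

    def __repr__(self):
        return f"ExpPoly({len(self.terms)} terms)"


def _term_antideriv(k: complex, p: int, c: complex) -> ExpPoly:
    if k == 0:
        return ExpPoly({(0.0 + 0.0j, p + 1): c / (p + 1)})
    if p == 0:
        return ExpPoly({(k, 0): c / k})
    return ExpPoly({(k, p): c / k}) + _term_antideriv(k, p - 1, -c * p / k)
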