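"""Dimensional context: converting reduced speeds back to laboratory units.

The solver works in dimensionless variables (lengths scaled by the filament
length L, time by the inverse angular forcing frequency 1/omega, moments by
A/L with A the bending modulus).  The reduced speed U strips both the small
forcing amplitude epsilon and the resistive-force drag anisotropy; the
laboratory swimming speed is

    U_lab = epsilon^2 * (c_perp - c_par) / (2 c_par) * U * L * omega .

The sperm number follows from the same parameters as Sp = L / l_e with the
elastic penetration length l_e = (A / (omega c_perp))^{1/4}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exceptions import InvalidParameterError

__all__ = ["DimensionalContext", "redimensionalize"]


@dataclass(frozen=True)
class DimensionalContext:
    """Physical parameters of a filament swimmer.

    Parameters
    ----------
    length_l : float
        Filament length L in metres.
    angular_freq : float
        Forcing angular frequency omega in rad/s.
    bending_a : float
        Bending modulus A in N m^2.
    drag_perp, drag_par : float
        Resistive-force drag coefficients c_perp, c_par in N s/m^2.
    amplitude_eps : float
        Dimensionless forcing amplitude epsilon.
    """

    length_l: float
    angular_freq: float
    bending_a: float
    drag_perp: float
    drag_par: float
    amplitude_eps: float

    def __post_init__(self):
        for name in ("length_l", "angular_freq", "bending_a", "drag_perp", "drag_par", "amplitude_eps"):
            if getattr(self, name) <= 0.0:
                raise InvalidParameterError(f"{name} must be positive")

    @property
    def penetration_length(self) -> float:
        """Elastic penetration length l_e = (A / (omega c_perp))^{1/4} in metres."""
        return (self.bending_a / (self.angular_freq * self.drag_perp)) ** 0.25

    @property
    def sperm_number(self) -> float:
        """Sp = L / l_e."""
        return self.length_l / self.penetration_length


def redimensionalize(ctx: DimensionalContext, reduced_u: float) -> float:
    """Laboratory swimming speed in m/s from a reduced speed U.

    Applies the drag-anisotropy prefactor (c_perp - c_par) / (2 c_par), the
    epsilon^2 amplitude scaling and the L*omega velocity scale.  Isotropic
    drag (c_perp == c_par) cannot produce thrust at this order; a warning is
    emitted and zero returned.
    """
    if ctx.drag_perp == ctx.drag_par:
        warnings.warn(
            "isotropic drag (c_perp == c_par) produces zero thrust at leading order",
            stacklevel=2,
        )
        return 0.0
    factor = (ctx.drag_perp - ctx.drag_par) / (2.0 * ctx.drag_par)
    return ctx.amplitude_eps**2 * factor * reduced_u * ctx.length_l * ctx.angular_freq
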