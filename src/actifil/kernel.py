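"""Swimming-speed kernel, shape reconstruction and the time-average speed oracle.

For time-harmonic forcing the reduced swimming speed is a bilinear form of
the forcing magnitude,

    U = int int f(xi1) Gswim(xi1, xi2) f(xi2) dxi2 dxi1,

with the real symmetric swimming-speed function assembled from the first
s-derivative of the Green's function,

    Gs(xi1, xi2) = -1/2 (Im[G'(xi1; xi2)] + Im[G'(xi2; xi1)]),
    Ga(xi1, xi2) = -1/2 (Re[G'(xi1; xi2)] - Re[G'(xi2; xi1)]),
    Gswim        = Gs cos(phi(xi1) - phi(xi2)) + Ga sin(phi(xi1) - phi(xi2)).

``Gs`` is symmetric and ``Ga`` antisymmetric, so ``Gswim`` is symmetric for
any phase function.  The same speed can be obtained independently by
reconstructing the filament motion and time-averaging
``U = -2 int <Psi_sss Psi_sst> ds``; :func:`speed_time_average_oracle`
implements that second route as a cross-check of the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import simpson

from .exceptions import InvalidParameterError
from .greens import GreensFunction, _gauss_panel, build_greens, solve_amplitude
from .profiles import ForcingProfile, constant_phase

__all__ = [
    "SpeedKernel",
    "FilamentShape",
    "compute_kernels",
    "speed_quadrature",
    "filament_shape",
    "speed_time_average_oracle",
]


def _first_arg_derivative_matrix(g: GreensFunction, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """D[i, j] = dG/ds (s = x1[i]; xi = x2[j])."""
    x1 = np.clip(np.asarray(x1, dtype=float), 0.0, 1.0)
    x2 = np.clip(np.asarray(x2, dtype=float), 1e-12, 1.0 - 1e-12)
    return g.evaluate(x1[:, None], x2[None, :], order=1)


def _gs_ga(g: GreensFunction, x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d12 = _first_arg_derivative_matrix(g, x1, x2)
    if x1.shape == x2.shape and np.array_equal(x1, x2):
        d21 = d12  # square case: one batched solve covers both orderings
    else:
        d21 = _first_arg_derivative_matrix(g, x2, x1)
    gs = -0.5 * (d12.imag + d21.imag.T)
    ga = -0.5 * (d12.real - d21.real.T)
    return gs, ga


@dataclass(frozen=True)
class SpeedKernel:
    """Sampled swimming-speed function on midpoint quadrature nodes.

    ``nodes`` are ``(2n - 1) / (2N)`` for ``n = 1..N``; ``gswim_matrix`` is the
    symmetrized kernel and the bilinear midpoint rule
    ``U = f^T Gswim f / N^2`` gives the reduced speed of a continuous profile.
    """

    sp: float
    n: int
    nodes: np.ndarray
    gs_matrix: np.ndarray
    ga_matrix: np.ndarray
    gswim_matrix: np.ndarray
    phase: Callable[[np.ndarray], np.ndarray]
    greens: GreensFunction

    def kernel_value(self, x1, x2) -> np.ndarray:
        """Gswim evaluated exactly at arbitrary coordinate pairs (no snapping)."""
        x1 = np.atleast_1d(np.asarray(x1, dtype=float))
        x2 = np.atleast_1d(np.asarray(x2, dtype=float))
        gs, ga = _gs_ga(self.greens, x1, x2)
        p1 = np.asarray(self.phase(x1), dtype=float)[:, None]
        p2 = np.asarray(self.phase(x2), dtype=float)[None, :]
        return gs * np.cos(p1 - p2) + ga * np.sin(p1 - p2)


def midpoint_nodes(n: int) -> np.ndarray:
    return (2.0 * np.arange(1, n + 1) - 1.0) / (2.0 * n)


def compute_kernels(sp: float, phase=None, n: int = 100, greens: GreensFunction | None = None) -> SpeedKernel:
    """Build Gs, Ga and Gswim sampled on the N midpoint nodes."""
    n = int(n)
    if n < 10:
        raise InvalidParameterError(f"need at least 10 quadrature nodes, got {n}")
    phase = phase or constant_phase()
    g = greens if greens is not None else build_greens(sp)
    nodes = midpoint_nodes(n)
    gs, ga = _gs_ga(g, nodes, nodes)
    if not (np.all(np.isfinite(gs)) and np.all(np.isfinite(ga))):
        raise InvalidParameterError(f"non-finite kernel entries at sp={sp}")
    # enforce the exact parity structure (floating-point residuals only)
    gs = 0.5 * (gs + gs.T)
    ga = 0.5 * (ga - ga.T)
    p = np.asarray(phase(nodes), dtype=float)
    dphi = p[:, None] - p[None, :]
    gswim = gs * np.cos(dphi) + ga * np.sin(dphi)
    gswim = 0.5 * (gswim + gswim.T)
    return SpeedKernel(
        sp=float(g.sp), n=n, nodes=nodes, gs_matrix=gs, ga_matrix=ga,
        gswim_matrix=gswim, phase=phase, greens=g,
    )


def speed_quadrature(kernel: SpeedKernel, forcing: ForcingProfile) -> float:
    """Reduced swimming speed U from the kernel bilinear form.

    Continuous profiles use the midpoint rule on the kernel nodes; discrete
    actuators use exact kernel evaluation at the actuator coordinates.
    """
    if forcing.kind == "discrete":
        locs, strengths = forcing.actuator_arrays()
        gsw = kernel.kernel_value(locs, locs)
        return float(strengths @ gsw @ strengths)
    f = forcing.magnitude(kernel.nodes)
    if f.shape != kernel.nodes.shape:
        raise InvalidParameterError("forcing samples do not match the kernel nodes")
    return float(f @ kernel.gswim_matrix @ f) / kernel.n**2


@dataclass(frozen=True)
class FilamentShape:
    """Leading-order filament motion reconstructed from the Green's function.

    ``psi_cap[o]`` holds the o-th s-derivative of the complex amplitude Phi on
    ``s_grid``; the real fields are ``y = Re[e^{it} Phi'']`` (vertical
    position), ``tangent_angle = Re[e^{it} Phi''']``, the tip velocity
    ``V(t) = Psi_sst(0, t)`` and the global torque ``int Psi_sst s ds``
    (identically zero for a free swimmer).
    """

    sp: float
    s_grid: np.ndarray
    t_grid: np.ndarray
    psi_cap: np.ndarray
    y: np.ndarray
    tangent_angle: np.ndarray
    tip_velocity: np.ndarray
    torque: np.ndarray


def _torque_amplitude(g: GreensFunction, forcing: ForcingProfile, quad_order: int = 64) -> complex:
    """int_0^1 s Phi''(s) ds by Gauss-Legendre, split at actuator corners."""
    if forcing.kind == "discrete":
        locs, _ = forcing.actuator_arrays()
        edges = np.unique(np.concatenate(([0.0], np.sort(locs), [1.0])))
    elif forcing.segments is not None:
        edges = np.asarray(forcing.segments[0], dtype=float)
    else:
        edges = np.array([0.0, 1.0])
    total = 0.0 + 0.0j
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 1e-14:
            continue
        nodes, weights = _gauss_panel(np.array(a), np.array(b), quad_order)
        nodes, weights = nodes.ravel(), weights.ravel()
        phi2 = solve_amplitude(g, forcing, nodes, orders=(2,))[0]
        total += np.sum(weights * nodes * phi2)
    return complex(total)


def filament_shape(sp: float, forcing: ForcingProfile, s_grid, t_grid) -> FilamentShape:
    """Reconstruct y, tangent angle, tip velocity and torque on (s, t) grids."""
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid.size < 2 or (t_grid.max() - t_grid.min()) < 2.0 * np.pi * (1.0 - 2.0 / t_grid.size):
        raise InvalidParameterError("t_grid must span at least one forcing period [0, 2 pi)")
    g = build_greens(sp)
    psi_cap = solve_amplitude(g, forcing, s_grid, orders=(0, 1, 2, 3))
    eit = np.exp(1j * t_grid)[:, None]
    y = np.real(eit * psi_cap[2][None, :])
    tangent = np.real(eit * psi_cap[3][None, :])
    phi2_tip = solve_amplitude(g, forcing, np.array([0.0]), orders=(2,))[0, 0]
    tip_velocity = np.real(1j * np.exp(1j * t_grid) * phi2_tip)
    torque_amp = _torque_amplitude(g, forcing)
    torque = np.real(1j * np.exp(1j * t_grid) * torque_amp)
    return FilamentShape(
        sp=float(sp), s_grid=s_grid, t_grid=t_grid, psi_cap=psi_cap,
        y=y, tangent_angle=tangent, tip_velocity=tip_velocity, torque=torque,
    )


def speed_time_average_oracle(shape: FilamentShape) -> float:
    """Reduced speed U = -2 int <Psi_sss Psi_sst> ds from the sampled motion.

    Time-averages the product of the sampled tangent-angle field and its time
    derivative over one period (uniform sampling makes the trapezoid average
    exact for trigonometric signals), then integrates in s by Simpson's rule
    on the shape's s-grid.  Independent of the kernel double-quadrature path.
    """
    t = shape.t_grid
    if t.size < 64:
        raise InvalidParameterError("time-average oracle needs at least 64 time samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise InvalidParameterError("time-average oracle needs uniform time sampling")
    eit = np.exp(1j * t)[:, None]
    psi_sss = np.real(eit * shape.psi_cap[3][None, :])
    psi_sst = np.real(1j * eit * shape.psi_cap[2][None, :])
    mean_product = np.mean(psi_sss * psi_sst, axis=0)
    return float(-2.0 * simpson(mean_product, x=shape.s_grid))
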