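"""Independent finite-difference solver for the time-harmonic filament problem.

This is a verification path only: it discretizes

    Sp^4 i Phi + Phi'''' = f(s) e^{-i phi(s)},   Phi = Phi' = 0 at s = 0, 1,

with a standard second-order five-point stencil on a uniform grid and ghost
nodes eliminated through the clamped end conditions.  The analytic
Green's-function pipeline never calls this module; the test suite uses it to
cross-check :mod:`actifil.greens` on the same problems.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import ConditioningError, InvalidParameterError
from .profiles import ForcingProfile

__all__ = ["bvp_oracle", "greens_oracle"]

_MIN_RESOLUTION = 200


def _hyperdiffusion_matrix(sperm: float, resolution: int) -> tuple[sp.csc_matrix, float]:
    """Sparse operator for Sp^4 i Phi + Phi'''' on nodes 0..resolution."""
    m = int(resolution)
    if m < _MIN_RESOLUTION:
        raise InvalidParameterError(f"resolution must be >= {_MIN_RESOLUTION}, got {m}")
    h = 1.0 / m
    n = m + 1
    rows, cols, vals = [], [], []
    for i in range(1, m):
        stencil = {i - 2: 1.0, i - 1: -4.0, i: 6.0, i + 1: -4.0, i + 2: 1.0}
        # ghost nodes: Phi(-1) = Phi(1), Phi(m+1) = Phi(m-1) from Phi'(0)=Phi'(1)=0
        fold = {}
        for j, v in stencil.items():
            jj = -j if j < 0 else (2 * m - j if j > m else j)
            fold[jj] = fold.get(jj, 0.0) + v
        for j, v in fold.items():
            rows.append(i)
            cols.append(j)
            vals.append(v / h**4)
        rows.append(i)
        cols.append(i)
        vals.append(sperm**4 * 1j)
    # boundary rows: Phi(0) = Phi(m) = 0
    for i in (0, m):
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
    a = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return a, h


def bvp_oracle(sperm: float, forcing: ForcingProfile, resolution: int = 2000):
    """Finite-difference amplitude table Phi on a uniform grid.

    Returns ``(s_grid, phi)`` with ``s_grid`` the uniform nodes (including the
    clamped ends) and ``phi`` the complex amplitude.  Point actuators are
    represented as discrete deltas of weight ``F/h`` at the nearest node.
    """
    if not np.isfinite(sperm) or sperm <= 0.0:
        raise InvalidParameterError(f"sperm number must be positive, got {sperm}")
    a, h = _hyperdiffusion_matrix(sperm, resolution)
    n = a.shape[0]
    s_grid = np.linspace(0.0, 1.0, n)
    rhs = np.zeros(n, dtype=complex)
    if forcing.kind == "continuous":
        rhs[1:-1] = forcing.complex_forcing(s_grid[1:-1])
    else:
        locs, strengths = forcing.actuator_arrays()
        phases = np.exp(-1j * np.asarray(forcing.phase(locs), dtype=float))
        for loc, f_m, ph in zip(locs, strengths, phases):
            idx = int(round(loc / h))
            idx = min(max(idx, 1), n - 2)
            rhs[idx] += f_m * ph / h
    try:
        phi = spla.spsolve(a, rhs)
    except RuntimeError as exc:  # pragma: no cover - singular discrete system
        raise ConditioningError(f"singular finite-difference system at sp={sperm}") from exc
    if not np.all(np.isfinite(phi)):
        raise ConditioningError(f"finite-difference solve produced non-finite values at sp={sperm}")
    return s_grid, phi


def greens_oracle(sperm: float, xi: float, resolution: int = 2000):
    """Finite-difference approximation of G(s; xi) on the uniform grid.

    ``xi`` is snapped to the nearest grid node (the discrete delta lives
    there), so pass source points commensurate with the resolution.
    """
    forcing = ForcingProfile.from_actuators([(float(xi), 1.0)])
    return bvp_oracle(sperm, forcing, resolution)
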