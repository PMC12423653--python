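"""Internal moment-forcing profiles.

A forcing profile represents the time-harmonic internal moment
``m(s, t) = Re[f(s) exp(-i phi(s)) exp(i t)]`` driving the filament: ``f``
is the real forcing magnitude and ``phi`` the phase along the arc length
``s in [0, 1]``.  Profiles are either continuous (``f`` a function or a
sampled table) or discrete (a list of point actuators, i.e. delta-function
moments of given strength).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "ForcingProfile",
    "constant_phase",
    "travelling_wave_phase",
    "fixture_profiles",
    "FIXTURE_NAMES",
]

DEFAULT_FIXTURE_SEED = 20240256


def constant_phase(value: float = 0.0) -> Callable[[np.ndarray], np.ndarray]:
    """Monophasic phase function phi(xi) = value (default 0)."""

    def phi(xi):
        return np.full_like(np.asarray(xi, dtype=float), value)

    phi.is_zero = value == 0.0
    return phi


def travelling_wave_phase(k: float) -> Callable[[np.ndarray], np.ndarray]:
    """Travelling-wave phase phi(xi) = 2 pi k xi.

    ``k`` counts forcing wavelengths along the filament; k > 0 is a wave
    travelling from the proximal (s=0) to the distal (s=1) end.
    """

    def phi(xi):
        return 2.0 * np.pi * k * np.asarray(xi, dtype=float)

    phi.is_zero = k == 0.0
    phi.wavenumber = k
    return phi


@dataclass(frozen=True)
class ForcingProfile:
    """A forcing magnitude f(xi) with phase phi(xi), or point actuators.

    Parameters
    ----------
    kind : {"continuous", "discrete"}
    f : callable, optional
        Forcing magnitude on [0, 1] (continuous profiles).
    phase : callable, optional
        Phase function on [0, 1]; defaults to the monophasic phi = 0.
    actuators : sequence of (location, strength), optional
        Point actuators for discrete profiles; locations in [0, 1].
    """

    kind: str
    f: Callable[[np.ndarray], np.ndarray] | None = None
    phase: Callable[[np.ndarray], np.ndarray] = field(default_factory=constant_phase)
    actuators: tuple[tuple[float, float], ...] = ()
    #: for piecewise-constant profiles: (edges, values) with len(values) = len(edges) - 1;
    #: lets downstream integrals against analytic mode functions be evaluated exactly.
    segments: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "discrete"):
            raise InvalidParameterError(f"unknown profile kind {self.kind!r}")
        if self.kind == "continuous":
            if self.f is None:
                raise InvalidParameterError("continuous profile requires f")
        else:
            if not self.actuators:
                raise InvalidParameterError("discrete profile requires actuators")
            locs = np.array([a[0] for a in self.actuators], dtype=float)
            if np.any(locs < 0.0) or np.any(locs > 1.0):
                raise InvalidParameterError("actuator locations must lie in [0, 1]")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def from_function(cls, f, phase=None) -> "ForcingProfile":
        return cls(kind="continuous", f=f, phase=phase or constant_phase())

    @classmethod
    def from_samples(cls, xi, values, phase=None) -> "ForcingProfile":
        """Continuous profile linearly interpolated through (xi, values)."""
        xi = np.asarray(xi, dtype=float)
        values = np.asarray(values, dtype=float)
        if xi.ndim != 1 or xi.shape != values.shape or xi.size < 2:
            raise InvalidParameterError("need matching 1-d sample arrays of length >= 2")

        def f(x):
            return np.interp(np.asarray(x, dtype=float), xi, values)

        return cls(kind="continuous", f=f, phase=phase or constant_phase())

    @classmethod
    def from_actuators(cls, actuators: Sequence[tuple[float, float]], phase=None) -> "ForcingProfile":
        return cls(
            kind="discrete",
            phase=phase or constant_phase(),
            actuators=tuple((float(x), float(F)) for x, F in actuators),
        )

    # -- evaluation ----------------------------------------------------------------

    @property
    def is_monophasic(self) -> bool:
        return bool(getattr(self.phase, "is_zero", False))

    def magnitude(self, xi) -> np.ndarray:
        if self.kind != "continuous":
            raise InvalidParameterError("magnitude() is defined for continuous profiles")
        return np.asarray(self.f(np.asarray(xi, dtype=float)), dtype=float)

    def complex_forcing(self, xi) -> np.ndarray:
        """f(xi) exp(-i phi(xi)), the complex amplitude of the moment forcing."""
        xi = np.asarray(xi, dtype=float)
        return self.magnitude(xi) * np.exp(-1j * np.asarray(self.phase(xi), dtype=float))

    def actuator_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        locs = np.array([a[0] for a in self.actuators], dtype=float)
        strengths = np.array([a[1] for a in self.actuators], dtype=float)
        return locs, strengths


# -- fixture generator ---------------------------------------------------------------

FIXTURE_NAMES = ("constant", "sin", "piecewise", "actuators", "random")


def fixture_profiles(name: str, **params) -> ForcingProfile:
    """Deterministic library of forcing profiles used throughout the examples.

    ``constant``
        f(xi) = 1.
    ``sin``
        f(xi) = sin(2 pi * freq * xi); ``freq`` defaults to 1.
    ``piecewise``
        Piecewise-constant profile; ``breaks`` are interior breakpoints and
        ``values`` the value on each resulting segment (defaults: the
        front-half swimmer f = 1 on [0, 0.5], 0 after).
    ``actuators``
        Discrete profile from ``actuators=[(location, strength), ...]``.
    ``random``
        Smooth random profile: a low-order Fourier series with coefficients
        drawn uniformly from [-1, 1] (``seed`` defaults to 20240256,
        ``n_harmonics`` to 4).

    Any fixture accepts ``k`` to impose a travelling-wave phase phi = 2 pi k xi.
    """
    phase = travelling_wave_phase(params.pop("k")) if "k" in params else constant_phase()
    if name == "constant":
        return ForcingProfile.from_function(lambda xi: np.ones_like(np.asarray(xi, float)), phase)
    if name == "sin":
        freq = float(params.get("freq", 1.0))
        return ForcingProfile.from_function(
            lambda xi, _w=2.0 * np.pi * freq: np.sin(_w * np.asarray(xi, float)), phase
        )
    if name == "piecewise":
        breaks = np.asarray(params.get("breaks", [0.5]), dtype=float)
        values = np.asarray(params.get("values", [1.0, 0.0]), dtype=float)
        if values.size != breaks.size + 1:
            raise InvalidParameterError("need len(values) == len(breaks) + 1")
        edges = np.concatenate(([0.0], breaks, [1.0]))
        if np.any(np.diff(edges) <= 0):
            raise InvalidParameterError("breaks must be strictly increasing in (0, 1)")

        def f(x, _edges=edges, _vals=values):
            idx = np.clip(np.searchsorted(_edges, np.asarray(x, float), side="right") - 1, 0, _vals.size - 1)
            return _vals[idx]

        return ForcingProfile(kind="continuous", f=f, phase=phase, segments=(edges, values))
    if name == "actuators":
        return ForcingProfile.from_actuators(params["actuators"], phase)
    if name == "random":
        seed = int(params.get("seed", DEFAULT_FIXTURE_SEED))
        n_harm = int(params.get("n_harmonics", 4))
        rng = np.random.default_rng(seed)
        a0 = rng.uniform(-1.0, 1.0)
        ac = rng.uniform(-1.0, 1.0, n_harm)
        as_ = rng.uniform(-1.0, 1.0, n_harm)

        def f(x, _a0=a0, _ac=ac, _as=as_):
            x = np.asarray(x, dtype=float)
            out = np.full_like(x, _a0)
            for j in range(n_harm):
                out = out + _ac[j] * np.cos(2 * np.pi * (j + 1) * x)
                out = out + _as[j] * np.sin(2 * np.pi * (j + 1) * x)
            return out

        return ForcingProfile.from_function(f, phase)
    raise InvalidParameterError(f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}")
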