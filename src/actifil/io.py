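"""CSV/JSON serialization of kernels, spectra, shapes and configurations.

All floating-point output uses 17 significant digits so round-trips are
bit-exact; human-readable summaries elsewhere use 4.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError
from .kernel import FilamentShape, SpeedKernel
from .modal import ModalBasis
from .monophasic import AnalyticEigenSystem
from .profiles import ForcingProfile, constant_phase, travelling_wave_phase

__all__ = [
    "export_kernel_csv",
    "export_spectrum_csv",
    "export_eigenfunctions_csv",
    "export_monophasic_csv",
    "export_shape_frames",
    "read_profile_csv",
    "load_config",
    "dump_config",
]

_FLOAT_FMT = "%.17g"


def _write_frame(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def export_kernel_csv(kernel: SpeedKernel, path) -> Path:
    """Long-format kernel table with columns (xi1, xi2, gs, ga, gswim)."""
    n = kernel.n
    x1 = np.repeat(kernel.nodes, n)
    x2 = np.tile(kernel.nodes, n)
    df = pd.DataFrame({
        "xi1": x1,
        "xi2": x2,
        "gs": kernel.gs_matrix.ravel(),
        "ga": kernel.ga_matrix.ravel(),
        "gswim": kernel.gswim_matrix.ravel(),
    })
    return _write_frame(df, path)


def export_spectrum_csv(basis: ModalBasis, path) -> Path:
    df = pd.DataFrame({"rank": np.arange(1, basis.n + 1), "eigenvalue": basis.eigenvalues})
    return _write_frame(df, path)


def export_eigenfunctions_csv(basis: ModalBasis, path, n_modes: int = 6) -> Path:
    cols = {"node": basis.nodes}
    for j in range(min(n_modes, basis.n)):
        cols[f"g{j + 1}"] = basis.eigenfunctions[:, j]
    return _write_frame(pd.DataFrame(cols), path)


def export_monophasic_csv(system: AnalyticEigenSystem, path, n_points: int = 201) -> Path:
    """Profiles of g+, g- and their symmetric/antisymmetric doubles."""
    s = np.linspace(0.0, 1.0, n_points)
    df = pd.DataFrame({
        "s": s,
        "gplus": system.gplus(s),
        "gminus": system.gminus(s),
        "gs": system.gs(s),
        "ga": system.ga(s),
    })
    return _write_frame(df, path)


def export_shape_frames(shape: FilamentShape, path) -> Path:
    """Long-format animation table (frame, s, x, y); x = s at leading order."""
    frames = []
    for i, _t in enumerate(shape.t_grid):
        frames.append(pd.DataFrame({
            "frame": i,
            "s": shape.s_grid,
            "x": shape.s_grid,
            "y": shape.y[i],
        }))
    return _write_frame(pd.concat(frames, ignore_index=True), path)


def read_profile_csv(path, phase=None) -> ForcingProfile:
    """Continuous profile from a CSV with columns (xi, f)."""
    df = pd.read_csv(path)
    if not {"xi", "f"} <= set(df.columns):
        raise InvalidParameterError(f"{path}: expected columns 'xi' and 'f'")
    return ForcingProfile.from_samples(df["xi"].to_numpy(), df["f"].to_numpy(), phase=phase)


# ---------------------------------------------------------------- configuration

_DEFAULT_CONFIG = {
    "sp": 4.7,
    "n": 100,
    "phase": {"type": "constant", "k": 0.0},
    "profile": {"name": "constant"},
    "optimizer": {"mode": "binary", "m": 1, "min_sep": 0.1, "strengths": "unit_total_l1"},
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """JSON configuration merged over defaults; CLI flags override the file."""
    cfg = json.loads(json.dumps(_DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = json.load(fh)
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update({k: v for k, v in val.items() if v is not None})
        else:
            cfg[key] = val
    return cfg


def dump_config(cfg: dict) -> str:
    return json.dumps(cfg, indent=2, sort_keys=True)


def phase_from_config(cfg: dict):
    ptype = cfg.get("type", "constant")
    if ptype == "constant":
        return constant_phase()
    if ptype == "travelling_wave":
        return travelling_wave_phase(float(cfg.get("k", 0.0)))
    raise InvalidParameterError(f"unknown phase type {ptype!r}")
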