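"""Pore-radius profiling of a substrate channel along a straight axis.

At stations spaced along a user-supplied axis the profiler finds, within a
search disc in the plane perpendicular to the axis, the centre maximising
the clearance

    r(p) = min_i ( |p - x_i| - r_i ),

i.e. the radius of the largest sphere centred at p that touches no atom's
vdW sphere.  The optimisation is a deterministic coarse-grid search
followed by local grid refinement.  A station whose best clearance is
negative is flagged "blocked".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .structures import Structure

__all__ = ["PoreProfile", "pore_radius_profile"]


@dataclass
class PoreProfile:
    stations: np.ndarray  # position along axis, A
    radius: np.ndarray  # max inscribed-sphere radius, A (clamped >= 0 when blocked)
    centre: np.ndarray  # (n, 3) in-plane optimum
    blocked: np.ndarray  # bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.stations) <= 0):
            raise ValueError("stations must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station": self.stations,
                "radius": self.radius,
                "cx": self.centre[:, 0],
                "cy": self.centre[:, 1],
                "cz": self.centre[:, 2],
                "blocked": self.blocked,
            }
        )


def _clearance(p: np.ndarray, coords: np.ndarray, radii: np.ndarray) -> float:
    d = np.sqrt(((coords - p) ** 2).sum(axis=1)) - radii
    return float(d.min())


def _plane_basis(axis_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis_dir @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis_dir, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    return u, v


def pore_radius_profile(
    s: Structure,
    axis: tuple[np.ndarray, np.ndarray],
    n_stations: int = 50,
    search_radius: float = 15.0,
    coarse_step: float = 0.5,
    fine_step: float = 0.02,
) -> PoreProfile:
    """Profile the maximal inscribed-sphere radius along a channel axis.

    Parameters
    ----------
    s
        Structure with per-atom vdW radii.
    axis
        Two distinct endpoint coordinates defining the straight pore axis.
    n_stations
        Number of evenly spaced stations between the endpoints (inclusive).
    search_radius
        Radius of the in-plane disc searched for the optimal centre.
    coarse_step, fine_step
        Grid spacings of the coarse search and the final refinement.
    """
    if len(s) == 0:
        raise ValueError("structure is empty")
    if s.vdw_radius is None:
        raise SchemaError("structure lacks vdW radii; call with_default_radii()")
    if n_stations < 1:
        raise ParameterError("n_stations must be >= 1")
    a, b = (np.asarray(p, dtype=float) for p in axis)
    span = b - a
    length = np.linalg.norm(span)
    if length < 1e-9:
        raise ParameterError("axis endpoints must be distinct")
    direction = span / length
    u, v = _plane_basis(direction)

    stations = np.linspace(0.0, length, n_stations)
    coords, radii = s.coords, s.vdw_radius
    radius_out = np.empty(n_stations)
    centre_out = np.empty((n_stations, 3))
    blocked = np.zeros(n_stations, dtype=bool)

    for k, t in enumerate(stations):
        origin = a + t * direction

        def point(du: float, dv: float) -> np.ndarray:
            return origin + du * u + dv * v

        # coarse disc grid, evaluated in one vectorised sweep
        g = np.arange(-search_radius, search_radius + 1e-9, coarse_step)
        gu, gv = np.meshgrid(g, g, indexing="ij")
        in_disc = gu**2 + gv**2 <= search_radius**2
        du_flat, dv_flat = gu[in_disc], gv[in_disc]
        pts = origin + du_flat[:, None] * u + dv_flat[:, None] * v
        d = np.sqrt(
            ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        ) - radii[None, :]
        vals = d.min(axis=1)
        ib = int(np.argmax(vals))
        best_val, best_uv = float(vals[ib]), (float(du_flat[ib]), float(dv_flat[ib]))
        # local refinement: shrink the step around the incumbent
        step = coarse_step
        cu, cv = best_uv
        while step > fine_step:
            step /= 2.0
            improved = True
            while improved:
                improved = False
                for du, dv in (
                    (cu + step, cv),
                    (cu - step, cv),
                    (cu, cv + step),
                    (cu, cv - step),
                    (cu + step, cv + step),
                    (cu + step, cv - step),
                    (cu - step, cv + step),
                    (cu - step, cv - step),
                ):
                    if du * du + dv * dv > search_radius**2:
                        continue
                    val = _clearance(point(du, dv), coords, radii)
                    if val > best_val + 1e-12:
                        best_val, (cu, cv) = val, (du, dv)
                        improved = True
        centre_out[k] = point(cu, cv)
        if best_val < 0:
            blocked[k] = True
            radius_out[k] = 0.0
        else:
            radius_out[k] = best_val
    return PoreProfile(
        stations=stations, radius=radius_out, centre=centre_out, blocked=blocked
    )
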