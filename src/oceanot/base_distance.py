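"""Base (ground) distances between support cells.

The transport cost between two distributions is built from a base-distance
matrix d_ij: great-circle kilometres between (lon, lat) cell centers for
surface maps, absolute depth differences in metres for vertical profiles.
Arcs can be forbidden (local-transport variants) by setting their base
distance to +inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scalar_fields import DepthAxis

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class BaseDistanceMatrix:
    """Pairwise base costs d_ij between source and target cells.

    ``d`` is an (m, n) matrix of non-negative distances (km for maps,
    m for profiles); +inf entries mark forbidden arcs.
    """

    d: np.ndarray
    units: str = "km"

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2:
            raise ValueError("base distance matrix must be 2-D")
        if np.any(np.isnan(d)) or np.any(d < 0):
            raise ValueError("base distances must be non-negative (inf allowed)")
        object.__setattr__(self, "d", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.d.shape


def great_circle_matrix(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    radius_km: float = EARTH_RADIUS_KM,
) -> BaseDistanceMatrix:
    """Great-circle distances (km) between two sets of (lon, lat) points.

    Uses the haversine formulation on a sphere of radius ``radius_km``,
    which is numerically stable for nearby points and exactly symmetric.
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("coordinates must be (n, 2) arrays of (lon, lat)")
    lon_a, lat_a = np.radians(a[:, 0])[:, None], np.radians(a[:, 1])[:, None]
    lon_b, lat_b = np.radians(b[:, 0])[None, :], np.radians(b[:, 1])[None, :]
    sin_dlat = np.sin((lat_b - lat_a) / 2.0)
    sin_dlon = np.sin((lon_b - lon_a) / 2.0)
    h = sin_dlat**2 + np.cos(lat_a) * np.cos(lat_b) * sin_dlon**2
    angle = 2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return BaseDistanceMatrix(radius_km * angle, units="km")


def depth_distance_matrix(axis_a: DepthAxis, axis_b: DepthAxis) -> BaseDistanceMatrix:
    """Absolute depth differences |z_i - z_j| in metres."""
    d = np.abs(axis_a.depths[:, None] - axis_b.depths[None, :])
    return BaseDistanceMatrix(d, units="m")


def mask_long_arcs(d: BaseDistanceMatrix, c: float) -> BaseDistanceMatrix:
    """Forbid arcs longer than ``c`` (same units as ``d``) by setting them to +inf.

    Restricting transport to local moves; feasibility under the mask is
    checked when the transport problem is solved, not here.
    """
    if c <= 0:
        raise ValueError("threshold c must be positive")
    masked = np.where(d.d > c, np.inf, d.d)
    return BaseDistanceMatrix(masked, units=d.units)
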