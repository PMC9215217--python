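"""Synthetic fields, map series and depth profiles with known structure.

Every downstream stage of the package is testable without any satellite or
model download: a smooth latitudinal chlorophyll front stands in for the
transition-zone background, a movable truncated-Gaussian patch reproduces
the patch-displacement toy experiment (RMSE saturates once the patches stop
overlapping, W2 keeps growing linearly with displacement), a seasonal map
series with optional long-term drift exercises the trend regression, and
unimodal profiles with a controllable deep chlorophyll maximum exercise the
depth analyses.  All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_distance import EARTH_RADIUS_KM
from .scalar_fields import DepthAxis, GridSpec, ProbabilityField, ScalarField, normalize_profile

#: km per degree of latitude on the IUGG sphere.
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


def default_toy_grid(step: float = 4.0) -> GridSpec:
    """Central-Pacific box used by the patch-displacement toy experiment."""
    return GridSpec.regular(-178.0, -102.0, -30.0, 38.0, step)


@dataclass(frozen=True)
class PatchSpec:
    """A truncated circular Gaussian chlorophyll patch.

    The patch is truncated at ``trunc_sigma`` standard deviations so two
    copies displaced far enough have exactly disjoint supports -- the
    mechanism behind RMSE saturation.  ``aspect``/``rotation_deg`` allow an
    elongated, rotated patch; the default is circular (rotation is then a
    no-op).
    """

    center: tuple[float, float] = (-150.0, -10.0)
    amplitude: float = 2.0
    width_km: float = 350.0
    aspect: float = 1.0
    rotation_deg: float = 0.0
    trunc_sigma: float = 3.0

    def __post_init__(self):
        if self.amplitude <= 0 or self.width_km <= 0:
            raise ValueError("patch amplitude and width must be positive")


def _patch_values(grid: GridSpec, patch: PatchSpec,
                  lon_shift: float = 0.0, extra_rotation: float = 0.0) -> np.ndarray:
    clon = patch.center[0] + lon_shift
    clat = patch.center[1]
    if not (grid.lons.min() <= clon <= grid.lons.max()
            and grid.lats.min() <= clat <= grid.lats.max()):
        raise ValueError(
            f"patch center ({clon:.1f}, {clat:.1f}) is off the grid"
        )
    lon2d = np.broadcast_to(grid.lons, grid.shape)
    lat2d = np.broadcast_to(grid.lats[:, None], grid.shape)
    # local tangent-plane offsets in km around the patch center
    dx = (lon2d - clon) * KM_PER_DEG * np.cos(np.radians(clat))
    dy = (lat2d - clat) * KM_PER_DEG
    ang = np.radians(patch.rotation_deg + extra_rotation)
    xr = np.cos(ang) * dx + np.sin(ang) * dy
    yr = -np.sin(ang) * dx + np.cos(ang) * dy
    r2 = (xr / (patch.width_km * patch.aspect)) ** 2 + (yr / patch.width_km) ** 2
    vals = patch.amplitude * np.exp(-0.5 * r2)
    vals[r2 > patch.trunc_sigma**2] = 0.0
    return vals


def make_background(
    grid: GridSpec,
    low: float = 0.05,
    high: float = 1.0,
    front_lat: float = 25.0,
    front_width_deg: float = 8.0,
) -> ScalarField:
    """Smooth north-high latitudinal chlorophyll front (logistic profile).

    Values rise monotonically with latitude from ``low`` to ``high``; at
    ``front_lat`` the field equals the midpoint of the two plateaus.  With
    ``high == low`` the field is constant.
    """
    lat2d = np.broadcast_to(grid.lats[:, None], grid.shape)
    vals = low + (high - low) / (1.0 + np.exp(-(lat2d - front_lat) / front_width_deg))
    return ScalarField(grid, np.array(vals))


def make_patch_series(
    background: ScalarField,
    patch: PatchSpec,
    shifts: np.ndarray,
    rotation_per_deg: float = 0.0,
) -> list[ScalarField]:
    """Background plus the patch displaced east by each longitude shift.

    ``rotation_per_deg`` optionally rotates the (anisotropic) patch by that
    many degrees per degree of shift; off by default.
    """
    out = []
    for s in np.asarray(shifts, dtype=float):
        vals = background.values + _patch_values(
            background.grid, patch, lon_shift=s,
            extra_rotation=rotation_per_deg * s,
        )
        out.append(ScalarField(background.grid, vals))
    return out


@dataclass(frozen=True)
class SeriesSpec:
    """Monthly map series: a patch whose position oscillates seasonally,
    optionally drifts over the years, and jitters with seeded noise.

    Displacement magnitudes are kilometres of longitude motion at the patch
    latitude; ``seed`` fixes all randomness.
    """

    start: tuple[int, int] = (1998, 1)
    n_months: int = 36
    seasonal_amplitude_km: float = 600.0
    drift_km_per_month: float = 0.0
    noise_km: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_months < 1:
            raise ValueError("series must cover at least one month")
        if min(self.seasonal_amplitude_km, self.noise_km) < 0:
            raise ValueError("magnitudes must be non-negative")

    def dates(self) -> list[tuple[int, int]]:
        y0, m0 = self.start
        return [(y0 + (m0 - 1 + t) // 12, (m0 - 1 + t) % 12 + 1)
                for t in range(self.n_months)]


def make_seasonal_series(
    spec: SeriesSpec,
    grid: GridSpec | None = None,
    patch: PatchSpec | None = None,
    background: ScalarField | None = None,
) -> list[tuple[tuple[int, int], ScalarField]]:
    """Dated monthly fields whose patch follows seasonality + drift + noise.

    The patch longitude at month t is
    ``center + (A sin(2 pi m/12) + r t + noise_t) / km-per-deg``; the same
    seed reproduces the identical series.
    """
    if grid is None:
        grid = default_toy_grid()
    if patch is None:
        patch = PatchSpec(center=(-140.0, -10.0), amplitude=2.0, width_km=300.0)
    if background is None:
        background = make_background(grid)
    rng = np.random.default_rng(spec.seed)
    km_per_deg_lon = KM_PER_DEG * np.cos(np.radians(patch.center[1]))
    out = []
    for t, date in enumerate(spec.dates()):
        month = date[1]
        disp_km = (
            spec.seasonal_amplitude_km * np.sin(2.0 * np.pi * month / 12.0)
            + spec.drift_km_per_month * t
            + (rng.normal(0.0, spec.noise_km) if spec.noise_km > 0 else 0.0)
        )
        vals = background.values + _patch_values(
            grid, patch, lon_shift=disp_km / km_per_deg_lon
        )
        out.append((date, ScalarField(grid, vals)))
    return out


def make_profile(
    axis: DepthAxis,
    dcm_depth: float = 96.0,
    width_m: float = 30.0,
    surface_level: float = 0.10,
    noise: float = 0.0,
    seed: int | None = None,
) -> ProbabilityField:
    """Unimodal chlorophyll depth profile with a controllable DCM.

    A Gaussian bump of unit height at ``dcm_depth`` sits on a small surface
    baseline; multiplicative lognormal noise (sd ``noise`` in log space)
    keeps values positive.  The result is normalized to sum to one.
    """
    if not axis.depths.min() <= dcm_depth <= axis.depths.max():
        raise ValueError("dcm_depth must lie within the axis range")
    z = axis.depths
    vals = surface_level * np.exp(-z / 200.0) + np.exp(
        -0.5 * ((z - dcm_depth) / max(width_m, 1e-9)) ** 2
    )
    if noise > 0:
        rng = np.random.default_rng(seed)
        vals = vals * np.exp(rng.normal(0.0, noise, size=vals.shape))
    return normalize_profile(vals, axis)
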