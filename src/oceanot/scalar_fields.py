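"""Gridded scalar fields, depth profiles and their probability normalizations.

The objects here are the common currency of the package: a :class:`GridSpec`
describes a longitude-latitude cell partition of an ocean region, a
:class:`ScalarField` holds one non-negative concentration value per cell
(e.g. chlorophyll-a in mg m^-3), and a :class:`ProbabilityField` is the
normalized version of such a field -- the discrete distribution that optimal
transport operates on.  Depth profiles use a :class:`DepthAxis` as their
support instead of a grid.

Cell ordering convention: cells are enumerated row-major with latitude
descending (north first) and longitude ascending.  Every field on a given
grid shares this ordering, so transport plans and distance matrices are
reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as _dc_field
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger("oceanot")

#: Tolerance on "probabilities sum to one".
PROB_SUM_TOL = 1e-12


class FieldError(ValueError):
    """Raised for invalid scalar-field or probability-field inputs."""


# ---------------------------------------------------------------------------
# supports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A rectilinear longitude-latitude grid with a validity mask.

    Parameters
    ----------
    lons : (nlon,) array
        Cell-center longitudes, degrees east in [-180, 180), ascending.
    lats : (nlat,) array
        Cell-center latitudes, degrees north in [-90, 90], descending
        (north first, matching the cell-order convention).
    mask : (nlat, nlon) bool array
        True for valid ocean cells; land and permanently excluded cells
        (e.g. a coastline buffer) are False.
    """

    lons: np.ndarray
    lats: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        lons = np.asarray(self.lons, dtype=float)
        lats = np.asarray(self.lats, dtype=float)
        if lats.size > 1 and lats[0] < lats[-1]:  # accept ascending input
            lats = lats[::-1]
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (lats.size, lons.size):
            raise FieldError(
                f"mask shape {mask.shape} does not match (nlat, nlon) = "
                f"({lats.size}, {lons.size})"
            )
        if np.any(lons < -180) or np.any(lons >= 180):
            raise FieldError("longitudes must lie in [-180, 180)")
        if np.any(np.abs(lats) > 90):
            raise FieldError("latitudes must lie in [-90, 90]")
        if not mask.any():
            raise FieldError("grid has no valid cells")
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_cells(self) -> int:
        return self.mask.size

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def cell_lons(self) -> np.ndarray:
        """Longitude of every cell, flattened in cell order."""
        return np.broadcast_to(self.lons, self.shape).ravel()

    @property
    def cell_lats(self) -> np.ndarray:
        """Latitude of every cell, flattened in cell order."""
        return np.broadcast_to(self.lats[:, None], self.shape).ravel()

    def valid_cell_coords(self) -> np.ndarray:
        """(n_valid, 2) array of (lon, lat) for valid cells, in cell order."""
        flat = self.mask.ravel()
        return np.column_stack([self.cell_lons[flat], self.cell_lats[flat]])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GridSpec)
            and np.array_equal(self.lons, other.lons)
            and np.array_equal(self.lats, other.lats)
            and np.array_equal(self.mask, other.mask)
        )

    def __hash__(self):  # frozen dataclass with arrays
        return hash((self.lons.tobytes(), self.lats.tobytes(), self.mask.tobytes()))

    @classmethod
    def regular(cls, lon_min, lon_max, lat_min, lat_max, step,
                mask: np.ndarray | None = None) -> "GridSpec":
        """Build a regular grid of cell centers with spacing ``step`` degrees."""
        lons = np.arange(lon_min, lon_max + step / 2, step)
        lats = np.arange(lat_max, lat_min - step / 2, -step)
        if mask is None:
            mask = np.ones((lats.size, lons.size), dtype=bool)
        return cls(lons, lats, mask)


@dataclass(frozen=True)
class DepthAxis:
    """Strictly increasing depths (m below surface) supporting a profile."""

    depths: np.ndarray

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=float)
        if depths.size == 0:
            raise FieldError("depth axis is empty")
        if np.any(depths < 0):
            raise FieldError("depths must be non-negative")
        if depths.size > 1 and np.any(np.diff(depths) <= 0):
            raise FieldError("depths must be strictly increasing")
        object.__setattr__(self, "depths", depths)

    @property
    def n(self) -> int:
        return self.depths.size

    def __eq__(self, other) -> bool:
        return isinstance(other, DepthAxis) and np.array_equal(self.depths, other.depths)

    def __hash__(self):
        return hash(self.depths.tobytes())


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalarField:
    """A non-negative concentration per grid cell; NaN marks missing data.

    The *support* of the field -- the cells that survive into the normalized
    probability distribution -- is the intersection of the grid mask with the
    finite entries of ``values``: clouds/missing pixels and masked cells are
    treated identically.
    """

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise FieldError(
                f"values shape {values.shape} does not match grid {self.grid.shape}"
            )
        finite = np.isfinite(values)
        if np.any(values[finite & self.grid.mask] < 0):
            raise FieldError("scalar field has negative values")
        object.__setattr__(self, "values", values)

    @property
    def support(self) -> np.ndarray:
        """(nlat, nlon) bool: valid cells with a finite value."""
        return self.grid.mask & np.isfinite(self.values)

    def support_values(self) -> np.ndarray:
        return self.values[self.support]

    def support_coords(self) -> np.ndarray:
        flat = self.support.ravel()
        return np.column_stack(
            [self.grid.cell_lons[flat], self.grid.cell_lats[flat]]
        )


@dataclass(frozen=True)
class ProbabilityField:
    """A discrete probability distribution on a geographic or depth support.

    ``probs[k]`` is the proportion of total mass in support cell ``k``.  For
    map fields, ``grid`` and ``cell_index`` (flat indices into the grid, in
    cell order) locate the support; for depth profiles, ``axis`` does.
    """

    probs: np.ndarray
    grid: GridSpec | None = None
    axis: DepthAxis | None = None
    cell_index: np.ndarray | None = None

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0:
            raise FieldError("probs must be a nonempty 1-D array")
        if np.any(~np.isfinite(probs)) or np.any(probs < 0):
            raise FieldError("probabilities must be finite and non-negative")
        if abs(probs.sum() - 1.0) > PROB_SUM_TOL:
            raise FieldError(
                f"probabilities sum to {probs.sum():.15g}, not 1 within {PROB_SUM_TOL}"
            )
        if (self.grid is None) == (self.axis is None):
            raise FieldError("exactly one of grid or axis must be given")
        if self.grid is not None:
            idx = np.asarray(self.cell_index, dtype=np.intp)
            if idx.shape != probs.shape:
                raise FieldError("cell_index must align with probs")
            object.__setattr__(self, "cell_index", idx)
        elif self.axis is not None and probs.size != self.axis.n:
            raise FieldError("probs must align with the depth axis")
        object.__setattr__(self, "probs", probs)

    @property
    def n(self) -> int:
        return self.probs.size

    @property
    def coords(self) -> np.ndarray:
        """Support coordinates: (n, 2) (lon, lat) for maps, (n,) depths for profiles."""
        if self.grid is not None:
            return np.column_stack(
                [self.grid.cell_lons[self.cell_index],
                 self.grid.cell_lats[self.cell_index]]
            )
        return self.axis.depths

    @property
    def depths(self) -> np.ndarray:
        if self.axis is None:
            raise FieldError("not a depth-profile field")
        return self.axis.depths

    def same_support(self, other: "ProbabilityField") -> bool:
        if (self.grid is None) != (other.grid is None):
            return False
        if self.grid is not None:
            return self.grid == other.grid and np.array_equal(
                self.cell_index, other.cell_index
            )
        return self.axis == other.axis


# ---------------------------------------------------------------------------
# in-situ samples and colocalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InSituSample:
    """One shipboard measurement: when, how deep, and the concentration."""

    timestamp: datetime
    depth: float
    value: float = np.nan  # NaN flags a missing measurement

    def __post_init__(self):
        ts = self.timestamp
        if isinstance(ts, date) and not isinstance(ts, datetime):
            ts = datetime(ts.year, ts.month, ts.day)
        object.__setattr__(self, "timestamp", pd.Timestamp(ts))
        if np.isfinite(self.value) and self.value < 0:
            raise FieldError("sample value must be non-negative or missing")


@dataclass(frozen=True)
class ColocalizationWindow:
    """Half-widths of the space-time averaging vicinity: +/-2 days, +/-5 m."""

    time_halfwidth_days: float = 2.0
    depth_halfwidth_m: float = 5.0

    def __post_init__(self):
        if self.time_halfwidth_days <= 0 or self.depth_halfwidth_m <= 0:
            raise FieldError("colocalization half-widths must be positive")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_field(field: ScalarField) -> ProbabilityField:
    """Normalize a scalar field to a probability distribution.

    Divides each valid cell value by the total over valid cells so the result
    sums to one; masked and missing cells are excluded from the support,
    while zero-valued valid cells stay in the support with probability 0.

    Raises
    ------
    FieldError
        If the total over valid cells is zero ("zero total mass") or any
        value is negative.
    """
    support = field.support
    if not support.any():
        raise FieldError("field has no valid cells")
    vals = field.values[support]
    total = vals.sum()
    if total <= 0:
        raise FieldError("zero total mass: cannot normalize an all-zero field")
    probs = vals / total
    probs = probs / probs.sum()  # exact renormalization against rounding
    idx = np.flatnonzero(support.ravel())
    return ProbabilityField(probs=probs, grid=field.grid, cell_index=idx)


def normalize_profile(values: np.ndarray, axis: DepthAxis) -> ProbabilityField:
    """Normalize per-depth concentrations to sum to one on ``axis``."""
    vals = np.asarray(values, dtype=float)
    if vals.shape != (axis.n,):
        raise FieldError("profile values must align with the depth axis")
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        raise FieldError("profile values must be finite and non-negative")
    total = vals.sum()
    if total <= 0:
        raise FieldError("zero total mass: cannot normalize an all-zero profile")
    probs = vals / total
    return ProbabilityField(probs=probs / probs.sum(), axis=axis)


def colocalize(
    model_records: Iterable[tuple],
    samples: Sequence[InSituSample],
    window: ColocalizationWindow = ColocalizationWindow(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average model records in a space-time vicinity of each in-situ sample.

    For each in-situ sample at (t, z), the colocalized model value is the
    unweighted arithmetic mean of model values with |dt| <= 2 days and
    |dz| <= 5 m (window boundaries inclusive).  Samples with no model record
    in the window are dropped and reported.

    Parameters
    ----------
    model_records : iterable of (timestamp, depth, value)
    samples : sequence of InSituSample
    window : ColocalizationWindow

    Returns
    -------
    matched : DataFrame with columns (timestamp, depth, insitu_value, model_value)
    dropped : DataFrame of samples with no window match

    Raises
    ------
    FieldError
        If no sample has any model record in its window.
    """
    recs = pd.DataFrame(model_records, columns=["timestamp", "depth", "value"])
    if recs.empty or len(samples) == 0:
        raise FieldError("model records and in-situ samples must be nonempty")
    recs["timestamp"] = pd.to_datetime(recs["timestamp"])
    t_rec = recs["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64")
    z_rec = recs["depth"].to_numpy(dtype=float)
    v_rec = recs["value"].to_numpy(dtype=float)

    dt_max = window.time_halfwidth_days * 86400e9  # ns
    rows, dropped_rows = [], []
    for s in samples:
        dt = np.abs(t_rec - s.timestamp.value)
        dz = np.abs(z_rec - s.depth)
        in_win = (dt <= dt_max) & (dz <= window.depth_halfwidth_m) & np.isfinite(v_rec)
        if in_win.any():
            rows.append((s.timestamp, s.depth, s.value, v_rec[in_win].mean()))
        else:
            dropped_rows.append((s.timestamp, s.depth, s.value))
    if not rows:
        raise FieldError(
            f"colocalization produced no matches for any of {len(samples)} samples"
        )
    matched = pd.DataFrame(rows, columns=["timestamp", "depth", "insitu_value", "model_value"])
    dropped = pd.DataFrame(dropped_rows, columns=["timestamp", "depth", "insitu_value"])
    if len(dropped):
        logger.info("colocalize: dropped %d of %d samples with no window match",
                    len(dropped), len(samples))
    return matched, dropped


def profile_from_samples(samples: Sequence[InSituSample], axis: DepthAxis) -> ProbabilityField:
    """Bin sample values to the nearest axis depth and normalize to sum 1.

    Multiple samples falling in the same bin are averaged; axis depths that
    receive no sample are excluded from the support.
    """
    vals = np.array([s.value for s in samples], dtype=float)
    deps = np.array([s.depth for s in samples], dtype=float)
    ok = np.isfinite(vals)
    if not ok.any():
        raise FieldError("all sample values missing")
    vals, deps = vals[ok], deps[ok]
    # nearest axis depth per sample
    bins = np.abs(deps[:, None] - axis.depths[None, :]).argmin(axis=1)
    binned = np.full(axis.n, np.nan)
    for b in np.unique(bins):
        binned[b] = vals[bins == b].mean()
    present = np.isfinite(binned)
    sub_axis = DepthAxis(axis.depths[present])
    return normalize_profile(binned[present], sub_axis)


# ---------------------------------------------------------------------------
# I/O: NetCDF (CF-style) and CSV
# ---------------------------------------------------------------------------

def field_to_dataset(field: ScalarField, name: str = "value") -> xr.Dataset:
    """Represent a scalar field as a CF-style xarray Dataset."""
    da = xr.DataArray(
        np.where(field.grid.mask, field.values, np.nan),
        coords={"lat": field.grid.lats, "lon": field.grid.lons},
        dims=("lat", "lon"),
        name=name,
    )
    ds = da.to_dataset()
    ds["mask"] = (("lat", "lon"), field.grid.mask.astype(np.int8))
    return ds


def write_field_netcdf(field: ScalarField, path, name: str = "value") -> None:
    """Write a field to NetCDF3 (engine='scipy'; needs no extra libraries)."""
    field_to_dataset(field, name).to_netcdf(path, engine="scipy")


def read_field_netcdf(path, name: str | None = None) -> ScalarField:
    """Read a CF-style NetCDF field (lat/lon coords, one data variable)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    if name is None:
        candidates = [v for v in ds.data_vars if v != "mask"]
        if len(candidates) != 1:
            raise FieldError(
                f"cannot infer data variable among {sorted(ds.data_vars)}; pass name="
            )
        name = candidates[0]
    da = ds[name]
    lat_name = "lat" if "lat" in da.coords else "latitude"
    lon_name = "lon" if "lon" in da.coords else "longitude"
    da = da.sortby(lat_name, ascending=False).sortby(lon_name)
    values = np.asarray(da.values, dtype=float)
    if "mask" in ds:
        mask = np.asarray(
            ds["mask"].sortby(lat_name, ascending=False).sortby(lon_name).values
        ).astype(bool)
    else:
        mask = np.isfinite(values)
    grid = GridSpec(da[lon_name].values, da[lat_name].values, mask)
    return ScalarField(grid, values)


def read_field_csv(path) -> ScalarField:
    """Read a field from CSV with columns lon, lat, value (one row per cell)."""
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"lon", "lat", "value"}
    if not need.issubset(df.columns):
        raise FieldError(f"field CSV must have columns {sorted(need)}")
    lons = np.sort(df["lon"].unique())
    lats = np.sort(df["lat"].unique())[::-1]
    values = np.full((lats.size, lons.size), np.nan)
    li = {v: k for k, v in enumerate(lats)}
    lo = {v: k for k, v in enumerate(lons)}
    for lon, lat, val in df[["lon", "lat", "value"]].itertuples(index=False):
        values[li[lat], lo[lon]] = val
    mask = np.isfinite(values)
    return ScalarField(GridSpec(lons, lats, mask), values)


def write_field_csv(field: ScalarField, path) -> None:
    flat = field.grid.mask.ravel()
    pd.DataFrame({
        "lon": field.grid.cell_lons[flat],
        "lat": field.grid.cell_lats[flat],
        "value": field.values.ravel()[flat],
    }).to_csv(path, index=False, float_format="%.17g")


def read_samples_csv(path) -> list[InSituSample]:
    """Read in-situ samples from CSV with columns date, depth, value."""
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"date", "depth", "value"}
    if not need.issubset(df.columns):
        raise FieldError(f"sample CSV must have columns {sorted(need)}")
    return [
        InSituSample(pd.Timestamp(r.date), float(r.depth), float(r.value))
        for r in df.itertuples(index=False)
    ]
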