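"""Province estimation and boundary comparison.

A chlorophyll map over a transition zone splits naturally into provinces --
a low-chlorophyll subtropical side and a high-chlorophyll subpolar side --
separated by a front.  K-means on the per-cell values recovers such a
partition; the discretized boundary between provinces becomes a uniform
probability field of its own, and the Wasserstein distance between two
boundary fields measures how far one front must move to match the other,
independently of any magnitude differences inside the provinces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .base_distance import BaseDistanceMatrix, great_circle_matrix
from .optimal_transport import TransportPlan, solve_transport
from .scalar_fields import GridSpec, ProbabilityField, ScalarField


@dataclass(frozen=True)
class ProvinceLabels:
    """Cluster label per cell: 1..K on valid cells, 0 elsewhere.

    Labels are renumbered so cluster 1 has the lowest mean value, making
    the output deterministic for a fixed seed.
    """

    grid: GridSpec
    labels: np.ndarray
    K: int
    seed: int

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int32)
        if labels.shape != self.grid.shape:
            raise ValueError("labels must match the grid shape")
        valid = labels[self.grid.mask]
        if np.any(valid < 1) or np.any(valid > self.K):
            raise ValueError("every valid cell must carry a label in 1..K")
        object.__setattr__(self, "labels", labels)

    def to_csv(self, path) -> None:
        flat = self.grid.mask.ravel()
        pd.DataFrame({
            "lon": self.grid.cell_lons[flat],
            "lat": self.grid.cell_lats[flat],
            "label": self.labels.ravel()[flat],
        }).to_csv(path, index=False)


def kmeans_provinces(
    field: ScalarField,
    K: int = 2,
    seed: int = 0,
    log10: bool = False,
    n_restarts: int = 10,
) -> ProvinceLabels:
    """Partition a map into K provinces by K-means on the cell values.

    The clustering feature is the raw scalar value of each cell (1-D);
    ``log10=True`` clusters log10 of the values instead, which can matter
    for strongly skewed concentrations.  Fixed seed and multiple restarts
    make the result reproducible.

    Raises
    ------
    ValueError
        If the valid cells hold fewer than K distinct values
        ("degenerate clustering").
    """
    support = field.support
    vals = field.values[support]
    if np.unique(vals).size < K:
        raise ValueError(
            f"degenerate clustering: fewer than K={K} distinct values"
        )
    feat = np.log10(np.maximum(vals, 1e-30)) if log10 else vals
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed, tol=1e-10)
    raw = km.fit_predict(feat.reshape(-1, 1))
    order = np.argsort([feat[raw == c].mean() for c in range(K)])
    renum = np.empty(K, dtype=np.int32)
    renum[order] = np.arange(1, K + 1)
    labels = np.zeros(field.grid.shape, dtype=np.int32)
    labels[support] = renum[raw]
    # every valid grid cell must be labeled; NaN holes would leave orphans
    orphan = field.grid.mask & ~support
    if orphan.any():
        raise ValueError(
            "field has missing values on valid grid cells; fill or mask them "
            "before clustering"
        )
    return ProvinceLabels(grid=field.grid, labels=labels, K=K, seed=seed)


def boundary_field(labels: ProvinceLabels) -> ProbabilityField:
    """Uniform probability field on the discretized province boundary.

    A boundary cell is a valid cell with at least one valid 4-neighbor of a
    different label (both sides of every interface), each carrying mass
    1 / (number of boundary cells).  Relabeling clusters leaves the result
    unchanged.

    Raises
    ------
    ValueError
        If all valid cells share one label (no boundary).
    """
    lab = labels.labels
    valid = labels.grid.mask
    boundary = np.zeros_like(valid)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb_lab = np.roll(lab, shift, axis=axis)
        nb_valid = np.roll(valid, shift, axis=axis)
        edge = np.zeros_like(valid)  # roll wraps; kill the wrapped border
        if axis == 0:
            sl = 0 if shift == 1 else -1
            edge[sl, :] = True
        else:
            sl = 0 if shift == 1 else -1
            edge[:, sl] = True
        differs = valid & nb_valid & (lab != nb_lab) & ~edge
        boundary |= differs
    if not boundary.any():
        raise ValueError("no province boundary: all valid cells share one label")
    idx = np.flatnonzero(boundary.ravel())
    probs = np.full(idx.size, 1.0 / idx.size)
    return ProbabilityField(probs=probs, grid=labels.grid, cell_index=idx)


@dataclass(frozen=True)
class BoundaryComparison:
    """Boundary-to-boundary Wasserstein comparison of two maps."""

    w2: float
    plan: TransportPlan
    labels_a: ProvinceLabels
    labels_b: ProvinceLabels


def boundary_distance(
    field_a: ScalarField,
    field_b: ScalarField,
    K: int = 2,
    seeds: tuple[int, int] = (0, 0),
    d: BaseDistanceMatrix | None = None,
    log10: bool = False,
) -> BoundaryComparison:
    """W2 (km) between the K-means province boundaries of two maps.

    Composes kmeans_provinces -> boundary_field -> solve_transport with
    great-circle base distances between the two boundary supports.
    """
    la = kmeans_provinces(field_a, K=K, seed=seeds[0], log10=log10)
    lb = kmeans_provinces(field_b, K=K, seed=seeds[1], log10=log10)
    ba = boundary_field(la)
    bb = boundary_field(lb)
    if d is None:
        d = great_circle_matrix(ba.coords, bb.coords)
    plan = solve_transport(ba, bb, d)
    return BoundaryComparison(w2=plan.w2, plan=plan, labels_a=la, labels_b=lb)


def boundary_mask_csv(bfield: ProbabilityField, path) -> None:
    """Export a boundary field as a (lon, lat, mass) CSV mask."""
    coords = bfield.coords
    pd.DataFrame({
        "lon": coords[:, 0], "lat": coords[:, 1], "mass": bfield.probs,
    }).to_csv(path, index=False, float_format="%.17g")
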