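"""Pixel-wise RMSE, pairwise distance matrices and classical MDS.

Where the Wasserstein distance quantifies *where* mass sits, the RMSE
quantifies per-cell magnitude mismatch; the two are complementary.  A
collection of fields is summarized by its N x N pairwise distance matrix,
which classical multidimensional scaling embeds into the plane so that
Euclidean distances between embedded points approximate the matrix entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .base_distance import BaseDistanceMatrix, depth_distance_matrix, great_circle_matrix
from .optimal_transport import solve_transport
from .scalar_fields import ProbabilityField


def rmse(P: ProbabilityField, Q: ProbabilityField) -> float:
    """Root-mean-squared per-cell difference: ((1/n) sum_i (P_i - Q_i)^2)^(1/2).

    Requires both distributions on the identical cell set; fields on
    different supports must be reconciled (regridded/colocalized) first.
    """
    if not P.same_support(Q):
        raise ValueError(
            "rmse requires identical supports; reconcile the fields onto "
            "the exact same cells first"
        )
    diff = P.probs - Q.probs
    return float(np.sqrt(np.mean(diff * diff)))


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise distances between fields."""

    labels: tuple
    D: np.ndarray

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError("matrix shape must match the number of labels")
        if np.any(D < 0) or not np.allclose(D, D.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric and non-negative")
        if np.any(np.abs(np.diag(D)) > 1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "D", D)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.D, index=list(map(str, self.labels)),
                     columns=list(map(str, self.labels))
                     ).to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


def pairwise_distance_matrix(
    fields: Sequence[ProbabilityField],
    metric: str = "wasserstein",
    labels: Sequence | None = None,
    d: BaseDistanceMatrix | None = None,
) -> DistanceMatrix:
    """All N(N-1)/2 unique pairwise distances between fields.

    For ``metric="wasserstein"`` on a shared support, the base-distance
    matrix is built once (great-circle for maps, |depth difference| for
    profiles) unless supplied via ``d``; distinct supports get a per-pair
    base matrix.  ``metric="rmse"`` requires a shared support.
    """
    n = len(fields)
    if n < 2:
        raise ValueError("need at least two fields")
    if labels is None:
        labels = tuple(range(n))
    if metric not in ("wasserstein", "rmse"):
        raise ValueError(f"unknown metric {metric!r}")

    shared = all(fields[0].same_support(f) for f in fields[1:])
    if metric == "wasserstein" and d is None and shared:
        d = _base_matrix(fields[0], fields[0])

    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            try:
                if metric == "rmse":
                    D[a, b] = rmse(fields[a], fields[b])
                else:
                    dab = d if (shared and d is not None) \
                        else _base_matrix(fields[a], fields[b])
                    D[a, b] = solve_transport(fields[a], fields[b], dab).w2
            except Exception as exc:
                raise RuntimeError(
                    f"distance failed for pair ({labels[a]!r}, {labels[b]!r}): {exc}"
                ) from exc
            D[b, a] = D[a, b]
    return DistanceMatrix(tuple(labels), D)


def _base_matrix(P: ProbabilityField, Q: ProbabilityField) -> BaseDistanceMatrix:
    if P.grid is not None and Q.grid is not None:
        return great_circle_matrix(P.coords, Q.coords)
    if P.axis is not None and Q.axis is not None:
        return depth_distance_matrix(P.axis, Q.axis)
    raise ValueError("cannot mix geographic and depth supports")


@dataclass(frozen=True)
class MDSEmbedding:
    """Planar configuration whose Euclidean distances approximate D.

    ``points`` is (N, dim); ``eigenvalues`` are all N eigenvalues of the
    doubly centred matrix, sorted descending (negative values diagnose
    non-Euclidean input).  ``stress`` is the rms error between embedded
    and input distances.
    """

    points: np.ndarray
    eigenvalues: np.ndarray
    stress: float
    labels: tuple

    def embedded_distances(self) -> np.ndarray:
        diff = self.points[:, None, :] - self.points[None, :, :]
        return np.sqrt((diff * diff).sum(axis=-1))

    def to_csv(self, path) -> None:
        pos = np.clip(self.eigenvalues, 0.0, None)
        share = (pos[: self.points.shape[1]] / pos.sum()
                 if pos.sum() > 0 else np.zeros(self.points.shape[1]))
        df = pd.DataFrame(self.points,
                          columns=[f"x{k+1}" for k in range(self.points.shape[1])])
        df.insert(0, "label", [str(l) for l in self.labels])
        for k, s in enumerate(share):
            df[f"eig_share_{k+1}"] = s
        df.to_csv(path, index=False, float_format="%.17g")


def classical_mds(D: DistanceMatrix, dim: int = 2) -> MDSEmbedding:
    """Classical (Torgerson) MDS of a distance matrix.

    Eigendecomposition of B = -1/2 J D^2 J (J the centring operator);
    the embedding uses the top ``dim`` eigenvectors scaled by the square
    roots of their eigenvalues.  Negative eigenvalues are clamped to zero
    (the standard convention for non-Euclidean input), and each axis is
    given a deterministic sign: its largest-magnitude coordinate is positive.
    """
    n = D.n
    if n < dim + 1:
        raise ValueError(f"need at least {dim + 1} points for a {dim}-D embedding")
    D2 = D.D * D.D
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    eig_floor = 1e-12 * max(float(np.abs(evals).max()), 1.0)
    n_pos = int(np.sum(evals[:dim] > eig_floor))
    if n_pos < dim:
        import warnings
        warnings.warn(
            f"only {n_pos} positive eigenvalues for a {dim}-D embedding; "
            "padding remaining coordinates with zeros"
        )
    lam = np.clip(evals[:dim], 0.0, None)
    lam[lam <= eig_floor] = 0.0  # padded axes are exactly zero
    points = evecs[:, :dim] * np.sqrt(lam)[None, :]
    for k in range(dim):  # deterministic sign convention
        col = points[:, k]
        if col.any() and col[np.argmax(np.abs(col))] < 0:
            points[:, k] = -col
    diff = points[:, None, :] - points[None, :, :]
    emb = np.sqrt((diff * diff).sum(axis=-1))
    iu = np.triu_indices(n, 1)
    stress = float(np.sqrt(np.mean((emb[iu] - D.D[iu]) ** 2)))
    return MDSEmbedding(points=points, eigenvalues=evals, stress=stress,
                        labels=D.labels)
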