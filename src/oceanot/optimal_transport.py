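"""Exact discrete optimal transport and the 2-Wasserstein distance.

Solves the transportation linear program

    minimize   sum_ij f_ij d_ij^2
    subject to f_ij >= 0,  sum_j f_ij = P_i,  sum_i f_ij = Q_j

for discrete distributions P (m cells) and Q (n cells) with base distances
d_ij, returning a basic optimal plan f-hat and the 2-Wasserstein distance
W2 = sqrt(optimal value).  The squared base cost makes W2 a metric whenever
d is one, with units of d itself (km for maps, m for depth profiles) --
"how far, on average, mass had to move".

The solver is a transportation simplex: a network simplex specialized to the
dense bipartite transportation polytope, with a Vogel-style initial basic
feasible solution and an epsilon-perturbation of the supplies for
anti-cycling.  Forbidden arcs (+inf base distance, the "local transport"
variant) are handled by a pre-solve max-flow feasibility check and a large
finite surrogate cost inside the simplex; a feasible instance never leaves
mass on a forbidden arc, and this is asserted after the solve.

Two independent oracles are provided for verification: a generic dense LP
solve (scipy linprog/HiGHS) and the closed-form quantile-function W2 for
one-dimensional supports.  They are test instruments, not alternative
production paths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog
from scipy.sparse.csgraph import maximum_flow

from .base_distance import BaseDistanceMatrix
from .scalar_fields import ProbabilityField

logger = logging.getLogger("oceanot")

#: Marginal sums must match to this tolerance after the one-time renormalization.
MASS_TOL = 1e-9
#: Marginals of a returned plan match P and Q at least this tightly.
MARGINAL_TOL = 1e-10


class UnbalancedMassError(ValueError):
    """Source and target masses differ beyond tolerance."""


class InfeasibleTransportError(ValueError):
    """No feasible plan exists (forbidden arcs disconnect the supports)."""


# ---------------------------------------------------------------------------
# transportation simplex
# ---------------------------------------------------------------------------

def _vogel_initial_basis(a, b, C):
    """Vogel's approximation: a near-optimal initial basic feasible solution.

    Returns arrays (arc_i, arc_j, arc_f) of exactly m + n - 1 basic arcs
    forming a spanning tree of the bipartite supply/demand graph.  On ties
    between an exhausted row and column, only the row is removed, so the
    tree property is preserved through degenerate allocations.
    """
    m, n = C.shape
    rem_a = a.astype(float).copy()
    rem_b = b.astype(float).copy()
    row_alive = np.ones(m, dtype=bool)
    col_alive = np.ones(n, dtype=bool)
    arc_i, arc_j, arc_f = [], [], []

    while len(arc_f) < m + n - 1:
        nra, nca = int(row_alive.sum()), int(col_alive.sum())
        if nra == 1:
            i = int(np.flatnonzero(row_alive)[0])
            for j in np.flatnonzero(col_alive):
                arc_i.append(i); arc_j.append(int(j)); arc_f.append(rem_b[j])
            break
        if nca == 1:
            j = int(np.flatnonzero(col_alive)[0])
            for i in np.flatnonzero(row_alive):
                arc_i.append(int(i)); arc_j.append(j); arc_f.append(rem_a[i])
            break

        Cr = np.where(col_alive[None, :], C, np.inf)
        Cc = np.where(row_alive[:, None], C, np.inf)
        two_r = np.partition(Cr, 1, axis=1)[:, :2]
        two_c = np.partition(Cc, 1, axis=0)[:2, :]
        pen_r = np.where(row_alive, two_r[:, 1] - two_r[:, 0], -np.inf)
        pen_c = np.where(col_alive, two_c[1, :] - two_c[0, :], -np.inf)
        # inf - finite (single remaining candidate) means "must allocate here"
        pen_r = np.where(np.isnan(pen_r), np.inf, pen_r)
        pen_c = np.where(np.isnan(pen_c), np.inf, pen_c)

        if pen_r.max() >= pen_c.max():
            i = int(np.argmax(pen_r))
            j = int(np.argmin(Cr[i]))
        else:
            j = int(np.argmax(pen_c))
            i = int(np.argmin(Cc[:, j]))
        f = min(rem_a[i], rem_b[j])
        arc_i.append(i); arc_j.append(j); arc_f.append(f)
        if rem_a[i] <= rem_b[j]:   # ties remove the row only (degenerate-safe)
            row_alive[i] = False
            rem_b[j] -= f
            rem_a[i] = 0.0
        else:
            col_alive[j] = False
            rem_a[i] -= f
            rem_b[j] = 0.0

    return (np.array(arc_i, dtype=np.intp),
            np.array(arc_j, dtype=np.intp),
            np.array(arc_f, dtype=float))


def _compute_duals(m, n, adj, C):
    """Dual potentials u, v with u_i + v_j = C_ij on every basic arc."""
    u = np.empty(m); v = np.empty(n)
    u[0] = 0.0
    seen = np.zeros(m + n, dtype=bool)
    seen[0] = True
    stack = [0]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if seen[nb]:
                continue
            seen[nb] = True
            if node < m:          # row -> col
                v[nb - m] = C[node, nb - m] - u[node]
            else:                 # col -> row
                u[nb] = C[nb, node - m] - v[node - m]
            stack.append(nb)
    return u, v


def _tree_path(adj, start, goal, n_nodes):
    """Node path start -> goal through the basis spanning tree (BFS)."""
    parent = np.full(n_nodes, -1, dtype=np.intp)
    parent[start] = start
    frontier = [start]
    while parent[goal] < 0:
        nxt = []
        for node in frontier:
            for nb in adj[node]:
                if parent[nb] < 0:
                    parent[nb] = node
                    nxt.append(nb)
        frontier = nxt
    path = [goal]
    while path[-1] != start:
        path.append(int(parent[path[-1]]))
    path.reverse()
    return path


def _tree_flows(m, n, arc_i, arc_j, a, b):
    """Exact basic flows for the spanning tree given unperturbed marginals.

    Leaf elimination: a leaf's single arc must carry the leaf's entire
    remaining supply/demand.  Exact up to float addition error.
    """
    n_arcs = arc_i.size
    deg = np.zeros(m + n, dtype=np.intp)
    node_arcs = [[] for _ in range(m + n)]
    for k in range(n_arcs):
        deg[arc_i[k]] += 1
        deg[m + arc_j[k]] += 1
        node_arcs[arc_i[k]].append(k)
        node_arcs[m + arc_j[k]].append(k)
    rem = np.concatenate([a, b]).astype(float)
    done_arc = np.zeros(n_arcs, dtype=bool)
    flows = np.zeros(n_arcs)
    leaves = [v for v in range(m + n) if deg[v] == 1]
    while leaves:
        leaf = leaves.pop()
        k = next((kk for kk in node_arcs[leaf] if not done_arc[kk]), None)
        if k is None:
            continue
        other = m + arc_j[k] if leaf < m else arc_i[k]
        flows[k] = rem[leaf]
        rem[other] -= rem[leaf]
        rem[leaf] = 0.0
        done_arc[k] = True
        deg[leaf] -= 1
        deg[other] -= 1
        if deg[other] == 1:
            leaves.append(int(other))
    return flows


def _transportation_simplex(a, b, C, *, eps_scale=1e-7):
    """Minimize sum f_ij C_ij over the transportation polytope.

    Returns (arc_i, arc_j, flows) for the final basis, with flows recomputed
    exactly for the unperturbed marginals (anti-cycling perturbs supplies by
    ``eps_scale * min positive mass`` during pivoting only).
    """
    m, n = C.shape
    if m == 1 or n == 1:
        if m == 1:
            return (np.zeros(n, dtype=np.intp), np.arange(n, dtype=np.intp), b.copy())
        return (np.arange(m, dtype=np.intp), np.zeros(m, dtype=np.intp), a.copy())

    eps = eps_scale * min(a[a > 0].min(), b[b > 0].min())
    a_p = a + eps
    b_p = b.copy()
    b_p[-1] += m * eps

    arc_i, arc_j, arc_f = _vogel_initial_basis(a_p, b_p, C)
    n_nodes = m + n
    adj = [dict() for _ in range(n_nodes)]
    for k in range(arc_i.size):
        adj[arc_i[k]][m + arc_j[k]] = k
        adj[m + arc_j[k]][arc_i[k]] = k

    c_scale = float(np.abs(C).max()) if C.size else 1.0
    opt_tol = 1e-11 * (1.0 + c_scale)
    max_iter = 200 * (m + n) + 1000

    for _ in range(max_iter):
        u, v = _compute_duals(m, n, adj, C)
        red = C - u[:, None] - v[None, :]
        k_enter = int(np.argmin(red))
        if red.flat[k_enter] >= -opt_tol:
            break
        ei, ej = divmod(k_enter, n)
        # cycle: entering arc ei -> (m+ej), then tree path (m+ej) -> ei
        path = _tree_path(adj, m + ej, ei, n_nodes)
        cyc_arcs, cyc_sign = [], []
        for t in range(len(path) - 1):
            cyc_arcs.append(adj[path[t]][path[t + 1]])
            cyc_sign.append(-1.0 if t % 2 == 0 else 1.0)
        minus = [kk for kk, s in zip(cyc_arcs, cyc_sign) if s < 0]
        theta_k = min(minus, key=lambda kk: (arc_f[kk], kk))
        theta = arc_f[theta_k]
        for kk, s in zip(cyc_arcs, cyc_sign):
            arc_f[kk] += s * theta
        # basis exchange: entering arc reuses the leaving arc's slot
        li, lj = int(arc_i[theta_k]), int(arc_j[theta_k])
        del adj[li][m + lj]
        del adj[m + lj][li]
        arc_i[theta_k], arc_j[theta_k], arc_f[theta_k] = ei, ej, theta
        adj[ei][m + ej] = theta_k
        adj[m + ej][ei] = theta_k
    else:
        raise RuntimeError(
            f"transportation simplex did not converge in {max_iter} pivots"
        )

    flows = _tree_flows(m, n, arc_i, arc_j, a, b)
    neg = flows < 0
    if np.any(flows[neg] < -1e-6 * max(a.max(), b.max())):
        raise RuntimeError("transportation simplex produced an infeasible basis")
    flows[neg] = 0.0
    return arc_i, arc_j, flows


# ---------------------------------------------------------------------------
# feasibility under forbidden arcs
# ---------------------------------------------------------------------------

def _check_feasible(p, q, allowed):
    """Max-flow feasibility of the transportation problem with forbidden arcs.

    Masses are scaled to integers (1e9 resolution; scipy's max-flow works in
    int32) -- the slack accepted covers rounding only, far below any genuine
    deficit.
    """
    m, n = allowed.shape
    scale = 10**9
    sup = np.round(p * scale).astype(np.int32)
    dem = np.round(q * scale).astype(np.int32)
    src, snk = m + n, m + n + 1
    rows_i, cols_j = np.nonzero(allowed)
    data = np.concatenate([
        sup, dem, np.full(rows_i.size, scale, dtype=np.int32)
    ])
    row_idx = np.concatenate([
        np.full(m, src), np.arange(m, m + n), rows_i
    ])
    col_idx = np.concatenate([
        np.arange(m), np.full(n, snk), m + cols_j
    ])
    graph = sp.csr_matrix(
        (data, (row_idx, col_idx)), shape=(m + n + 2, m + n + 2)
    )
    flow = maximum_flow(graph, src, snk).flow_value
    total = min(sup.sum(), dem.sum())
    return flow >= total - (m + n + 2)


# ---------------------------------------------------------------------------
# transport plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportPlan:
    """An optimal transport plan between two probability fields.

    ``i``/``j`` index the support cells of the source/target fields,
    ``mass`` holds the transported probability per arc (all > 0),
    ``arc_length`` the base distance of each arc.  ``objective`` is
    sum f_ij d_ij^2 (squared base-distance units) and ``w2`` its square
    root -- the 2-Wasserstein distance in base-distance units.
    """

    i: np.ndarray
    j: np.ndarray
    mass: np.ndarray
    arc_length: np.ndarray
    objective: float
    w2: float
    units: str
    source: ProbabilityField
    target: ProbabilityField

    @property
    def n_arcs(self) -> int:
        return self.mass.size

    @property
    def arcs(self) -> list[tuple[int, int, float]]:
        return list(zip(self.i.tolist(), self.j.tolist(), self.mass.tolist()))

    @property
    def moving(self) -> np.ndarray:
        """Boolean mask of arcs that actually displace mass (length > 0)."""
        return self.arc_length > 0

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        """(row, column) marginals of the plan on the full supports."""
        row = np.zeros(self.source.n)
        col = np.zeros(self.target.n)
        np.add.at(row, self.i, self.mass)
        np.add.at(col, self.j, self.mass)
        return row, col


def solve_transport(
    P: ProbabilityField,
    Q: ProbabilityField,
    d: BaseDistanceMatrix,
    *,
    mass_tol: float = MASS_TOL,
) -> TransportPlan:
    """Solve the transportation LP exactly and return the optimal plan.

    Parameters
    ----------
    P, Q : ProbabilityField
        Source and target distributions (each sums to 1).
    d : BaseDistanceMatrix
        Base distances, shape (P.n, Q.n); +inf entries forbid arcs.

    Raises
    ------
    UnbalancedMassError
        If the input masses differ beyond tolerance.
    InfeasibleTransportError
        If forbidden arcs make the problem infeasible.
    """
    if d.shape != (P.n, Q.n):
        raise ValueError(
            f"base distance shape {d.shape} does not match supports "
            f"({P.n}, {Q.n})"
        )
    p, q = P.probs.astype(float), Q.probs.astype(float)
    sp_, sq_ = p.sum(), q.sum()
    if abs(sp_ - sq_) > 1e-6:
        raise UnbalancedMassError(
            f"unbalanced masses: source sums to {sp_:.9g}, target to {sq_:.9g}"
        )
    if abs(sp_ - 1.0) > 1e-15 or abs(sq_ - 1.0) > 1e-15:
        logger.debug("solve_transport: renormalizing inputs by %.3e / %.3e",
                     sp_ - 1.0, sq_ - 1.0)
    p, q = p / sp_, q / sq_
    if abs(p.sum() - 1.0) > mass_tol or abs(q.sum() - 1.0) > mass_tol:
        raise UnbalancedMassError("masses do not sum to 1 after renormalization")

    # zero-probability cells cannot carry mass; drop them from the LP
    ip = np.flatnonzero(p > 0)
    iq = np.flatnonzero(q > 0)
    a, b = p[ip], q[iq]
    D = d.d[np.ix_(ip, iq)]
    C = D * D
    finite = np.isfinite(C)
    if not finite.all():
        if not _check_feasible(a, b, finite):
            raise InfeasibleTransportError(
                "no feasible transport: forbidden arcs disconnect the supports"
            )
        big = 1e8 * max(1.0, float(C[finite].max()) if finite.any() else 1.0)
        C = np.where(finite, C, big)

    ai, aj, af = _transportation_simplex(a, b, C)

    keep = af > 0
    ai, aj, af = ai[keep], aj[keep], af[keep]
    on_forbidden = ~finite[ai, aj]
    if np.any(af[on_forbidden] > 1e-12):
        raise InfeasibleTransportError(
            "no feasible transport: optimal plan required a forbidden arc"
        )
    if on_forbidden.any():
        ai, aj, af = ai[~on_forbidden], aj[~on_forbidden], af[~on_forbidden]

    i_full = ip[ai]
    j_full = iq[aj]
    lengths = d.d[i_full, j_full]
    objective = float(np.sum(af * lengths * lengths))
    w2 = float(np.sqrt(max(objective, 0.0)))

    plan = TransportPlan(
        i=i_full, j=j_full, mass=af, arc_length=lengths,
        objective=objective, w2=w2, units=d.units, source=P, target=Q,
    )
    row, col = plan.marginals()
    if (np.max(np.abs(row - p)) > MARGINAL_TOL
            or np.max(np.abs(col - q)) > MARGINAL_TOL):
        raise RuntimeError("internal error: plan marginals violate conservation")
    return plan


# ---------------------------------------------------------------------------
# independent oracles (test instruments)
# ---------------------------------------------------------------------------

def solve_transport_lp_oracle(
    P: ProbabilityField, Q: ProbabilityField, d: BaseDistanceMatrix
) -> float:
    """Optimal objective via a generic dense LP solve (verification only).

    Solves the identical transportation LP with scipy's HiGHS and returns
    the objective sum f_ij d_ij^2.  Intended for small instances.
    """
    p, q = P.probs / P.probs.sum(), Q.probs / Q.probs.sum()
    ip, iq = np.flatnonzero(p > 0), np.flatnonzero(q > 0)
    a, b = p[ip], q[iq]
    C = d.d[np.ix_(ip, iq)] ** 2
    m, n = C.shape
    finite = np.isfinite(C)
    bounds = [(0.0, None) if finite.flat[k] else (0.0, 0.0) for k in range(m * n)]
    cost = np.where(finite, C, 0.0).ravel()
    rows = []
    for i in range(m):
        r = np.zeros((m, n)); r[i, :] = 1.0
        rows.append(r.ravel())
    for j in range(n - 1):  # drop the redundant last column constraint
        r = np.zeros((m, n)); r[:, j] = 1.0
        rows.append(r.ravel())
    A_eq = np.array(rows)
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise InfeasibleTransportError(f"LP oracle failed: {res.message}")
    return float(res.fun)


def wasserstein_1d_oracle(P: ProbabilityField, Q: ProbabilityField) -> float:
    """Closed-form W2 between 1-D (depth-axis) distributions, in metres.

    Uses the quantile-function representation:
    W2^2 = integral_0^1 (F_P^{-1}(t) - F_Q^{-1}(t))^2 dt, evaluated exactly
    for discrete distributions by summing over the merged CDF breakpoints.
    """
    if P.axis is None or Q.axis is None:
        raise ValueError("the 1-D oracle requires depth-profile fields")
    x, p = P.depths, P.probs / P.probs.sum()
    y, q = Q.depths, Q.probs / Q.probs.sum()
    cp = np.cumsum(p)
    cq = np.cumsum(q)
    ts = np.unique(np.concatenate([[0.0], cp, cq, [1.0]]))
    ts = ts[(ts >= 0.0) & (ts <= 1.0)]
    mid = (ts[:-1] + ts[1:]) / 2.0
    w = ts[1:] - ts[:-1]
    xi = np.clip(np.searchsorted(cp, mid, side="left"), 0, x.size - 1)
    yi = np.clip(np.searchsorted(cq, mid, side="left"), 0, y.size - 1)
    return float(np.sqrt(np.sum(w * (x[xi] - y[yi]) ** 2)))


# ---------------------------------------------------------------------------
# plan summaries and export
# ---------------------------------------------------------------------------

def transport_summary(plan: TransportPlan, *, include_stationary: bool = False):
    """Per-arc table with geographic or depth endpoints, mass and length.

    By default only mass-moving arcs (positive base distance) are listed,
    so a zero-cost plan yields an empty table.
    """
    import pandas as pd

    sel = np.ones(plan.n_arcs, dtype=bool) if include_stationary else plan.moving
    if plan.source.grid is not None:
        sc = plan.source.coords
        tc = plan.target.coords
        return pd.DataFrame({
            "i": plan.i[sel], "j": plan.j[sel],
            "lon_i": sc[plan.i[sel], 0], "lat_i": sc[plan.i[sel], 1],
            "lon_j": tc[plan.j[sel], 0], "lat_j": tc[plan.j[sel], 1],
            "mass": plan.mass[sel], "arc_km": plan.arc_length[sel],
        })
    return pd.DataFrame({
        "i": plan.i[sel], "j": plan.j[sel],
        "depth_i": plan.source.depths[plan.i[sel]],
        "depth_j": plan.target.depths[plan.j[sel]],
        "mass": plan.mass[sel], "arc_m": plan.arc_length[sel],
    })


def pooled_transport_summary(plans):
    """Pool arc masses across plans by (source, target) endpoint.

    For depth-profile plans this aggregates the movement of mass between
    depths over many paired comparisons, exposing systematic shifts (e.g.
    one source's chlorophyll maximum sitting deeper than the other's).
    """
    import pandas as pd

    tables = [transport_summary(pl) for pl in plans]
    pooled = pd.concat(tables, ignore_index=True)
    keys = [c for c in pooled.columns if c.startswith(("lon_", "lat_", "depth_"))]
    out = pooled.groupby(keys, as_index=False)["mass"].sum()
    return out.sort_values("mass", ascending=False, ignore_index=True)


def top_mass_arcs(plan: TransportPlan, fraction: float = 0.10):
    """Split the moving arcs into the heaviest head and the remaining tail.

    The head is the smallest prefix (arcs sorted by mass descending, ties by
    (i, j) ascending) whose cumulative mass reaches ``fraction`` of the total
    moved mass -- the "top 10% of the masses" arrows of a transport map.
    Returns (top, rest) as per-arc tables.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    table = transport_summary(plan)
    if len(table) == 0:
        return table, table.copy()
    order = np.lexsort((table["j"].to_numpy(), table["i"].to_numpy(),
                        -table["mass"].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    cum = table["mass"].cumsum().to_numpy()
    total = cum[-1]
    n_top = int(np.searchsorted(cum, fraction * total - 1e-15) + 1)
    return table.iloc[:n_top].copy(), table.iloc[n_top:].reset_index(drop=True)


def plan_to_csv(plan: TransportPlan, path) -> None:
    transport_summary(plan).to_csv(path, index=False, float_format="%.17g")


def plan_to_geojson(plan: TransportPlan, path) -> None:
    """Write moving arcs as GeoJSON LineStrings with a mass property."""
    if plan.source.grid is None:
        raise ValueError("GeoJSON export requires geographic supports")
    table = transport_summary(plan)
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[r.lon_i, r.lat_i], [r.lon_j, r.lat_j]],
            },
            "properties": {"mass": r.mass, "arc_km": r.arc_km},
        }
        for r in table.itertuples(index=False)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
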