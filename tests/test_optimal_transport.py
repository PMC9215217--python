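"""Exact transport solver: oracles, metric axioms, conservation, summaries."""

import numpy as np
import pytest

from oceanot import (
    BaseDistanceMatrix,
    DepthAxis,
    InfeasibleTransportError,
    ProbabilityField,
    UnbalancedMassError,
    depth_distance_matrix,
    great_circle_matrix,
    mask_long_arcs,
    pooled_transport_summary,
    solve_transport,
    solve_transport_lp_oracle,
    top_mass_arcs,
    transport_summary,
    wasserstein_1d_oracle,
)
from conftest import random_profile


def pf(probs):
    """Probability field on an abstract 1-D support (indices as depths)."""
    probs = np.asarray(probs, dtype=float)
    return ProbabilityField(probs, axis=DepthAxis(np.arange(probs.size, dtype=float)))


def random_instance(rng, max_n=12):
    """Random (P, Q, d) with a planar-Euclidean (hence metric) base cost."""
    m, n = rng.integers(2, max_n + 1, size=2)
    pts_a = rng.uniform(0.0, 1.0, (m, 2))
    pts_b = rng.uniform(0.0, 1.0, (n, 2))
    d = BaseDistanceMatrix(
        np.linalg.norm(pts_a[:, None] - pts_b[None, :], axis=-1), units="km"
    )
    return pf(rng.dirichlet(np.ones(m))), pf(rng.dirichlet(np.ones(n))), d


class TestSolveTransport:
    def test_point_mass_to_point_mass(self):
        d = BaseDistanceMatrix(np.array([[250.0]]))
        plan = solve_transport(pf([1.0]), pf([1.0]), d)
        assert plan.w2 == 250.0
        assert plan.arcs == [(0, 0, 1.0)]

    def test_identical_distributions_zero_cost(self, rng):
        p = pf(rng.dirichlet(np.ones(8)))
        d = depth_distance_matrix(p.axis, p.axis)
        plan = solve_transport(p, p, d)
        assert plan.w2 == 0.0
        assert not plan.moving.any()

    def test_two_cell_split(self):
        # P=(1,0), Q=(.5,.5), 100 km apart: move 0.5 across
        d = BaseDistanceMatrix(np.array([[0.0, 100.0], [100.0, 0.0]]))
        plan = solve_transport(pf([1.0, 0.0]), pf([0.5, 0.5]), d)
        assert plan.objective == pytest.approx(5000.0, abs=1e-10)
        assert plan.w2 == pytest.approx(100.0 / np.sqrt(2.0), abs=1e-10)

    def test_unbalanced_masses_rejected(self):
        bad = ProbabilityField.__new__(ProbabilityField)
        object.__setattr__(bad, "probs", np.array([0.6, 0.6]))
        object.__setattr__(bad, "grid", None)
        object.__setattr__(bad, "axis", DepthAxis([0.0, 1.0]))
        object.__setattr__(bad, "cell_index", None)
        with pytest.raises(UnbalancedMassError, match="unbalanced"):
            solve_transport(bad, pf([0.5, 0.5]), BaseDistanceMatrix(np.zeros((2, 2))))

    def test_lp_oracle_agreement(self, rng):
        worst = 0.0
        for _ in range(100):
            P, Q, d = random_instance(rng)
            plan = solve_transport(P, Q, d)
            worst = max(worst, abs(plan.objective - solve_transport_lp_oracle(P, Q, d)))
        assert worst < 1e-9

    def test_marginal_conservation(self, rng):
        for _ in range(25):
            P, Q, d = random_instance(rng, max_n=15)
            row, col = solve_transport(P, Q, d).marginals()
            assert np.max(np.abs(row - P.probs)) < 1e-10
            assert np.max(np.abs(col - Q.probs)) < 1e-10

    def test_scale_law(self, rng):
        P, Q, d = random_instance(rng)
        base = solve_transport(P, Q, d).w2
        for s in (0.5, 3.0, 1e3):
            scaled = BaseDistanceMatrix(s * d.d, units=d.units)
            assert solve_transport(P, Q, scaled).w2 == pytest.approx(
                s * base, rel=1e-12
            )

    def test_metric_axioms_on_common_support(self, rng):
        pts = np.column_stack([rng.uniform(-170, -120, 20), rng.uniform(-20, 40, 20)])
        d = great_circle_matrix(pts, pts)
        grid_pf = lambda p: ProbabilityField(
            p, axis=DepthAxis(np.arange(20.0))
        )  # abstract support; base matrix carries the geometry
        for _ in range(10):
            P, Q, R = (grid_pf(rng.dirichlet(np.ones(20))) for _ in range(3))
            w_pq = solve_transport(P, Q, d).w2
            w_qp = solve_transport(Q, P, BaseDistanceMatrix(d.d.T, d.units)).w2
            w_pr = solve_transport(P, R, d).w2
            w_qr = solve_transport(Q, R, d).w2
            assert solve_transport(P, P, d).w2 == 0.0
            assert abs(w_pq - w_qp) < 1e-10
            assert w_pr <= w_pq + w_qr + 1e-8

    def test_zero_probability_cells_ignored(self):
        # the third source cell has no mass; its huge arc costs cannot matter
        d = BaseDistanceMatrix(np.array([[0.0, 10.0], [10.0, 0.0], [1e6, 1e6]]))
        plan = solve_transport(pf([0.6, 0.4, 0.0]), pf([0.4, 0.6]), d)
        assert plan.w2 == pytest.approx(np.sqrt(0.2 * 100.0))


class TestMaskedArcs:
    def test_feasible_under_mask(self):
        d = mask_long_arcs(
            BaseDistanceMatrix(np.array([[0.0, 10.0], [10.0, 0.0]])), 5.0
        )
        plan = solve_transport(pf([0.5, 0.5]), pf([0.5, 0.5]), d)
        assert plan.w2 == 0.0

    def test_infeasible_under_mask(self):
        d = mask_long_arcs(
            BaseDistanceMatrix(np.array([[0.0, 10.0], [10.0, 0.0]])), 5.0
        )
        with pytest.raises(InfeasibleTransportError, match="feasible"):
            solve_transport(pf([1.0, 0.0]), pf([0.0, 1.0]), d)

    def test_mask_changes_optimum_but_stays_feasible(self, rng):
        # local-transport constraint can only increase the objective
        P, Q, d = random_instance(rng, max_n=8)
        full = solve_transport(P, Q, d).w2
        c = float(np.quantile(d.d, 0.9))
        try:
            masked = solve_transport(P, Q, mask_long_arcs(d, c)).w2
        except InfeasibleTransportError:
            return
        assert masked >= full - 1e-10


class TestOneDimensionalOracle:
    def test_translation_equals_shift(self):
        probs = np.array([0.2, 0.5, 0.3])
        P = ProbabilityField(probs, axis=DepthAxis([50.0, 96.0, 150.0]))
        Q = ProbabilityField(probs, axis=DepthAxis([90.0, 136.0, 190.0]))
        assert wasserstein_1d_oracle(P, Q) == pytest.approx(40.0, abs=1e-12)
        plan = solve_transport(P, Q, depth_distance_matrix(P.axis, Q.axis))
        assert plan.w2 == pytest.approx(40.0, abs=1e-10)

    def test_point_masses(self):
        P = ProbabilityField([1.0], axis=DepthAxis([96.0]))
        Q = ProbabilityField([1.0], axis=DepthAxis([140.0]))
        assert wasserstein_1d_oracle(P, Q) == 44.0

    def test_identity(self, rng):
        P = random_profile(rng)
        assert wasserstein_1d_oracle(P, P) == 0.0

    def test_agreement_with_simplex(self, rng):
        worst = 0.0
        for _ in range(200):
            P, Q = random_profile(rng), random_profile(rng)
            w2 = solve_transport(P, Q, depth_distance_matrix(P.axis, Q.axis)).w2
            worst = max(worst, abs(w2 - wasserstein_1d_oracle(P, Q)))
        assert worst < 1e-8


class TestPlanSummaries:
    def _shifted_plan(self, masses, positions=None):
        masses = np.asarray(masses, dtype=float)
        n = masses.size
        x = np.arange(n, dtype=float) if positions is None else positions
        P = ProbabilityField(masses, axis=DepthAxis(x))
        Q = ProbabilityField(masses, axis=DepthAxis(x + 100.0))
        return solve_transport(P, Q, depth_distance_matrix(P.axis, Q.axis))

    def test_top_fraction_smallest_prefix(self):
        plan = self._shifted_plan([0.5, 0.3, 0.15, 0.05])
        top, rest = top_mass_arcs(plan, fraction=0.10)
        assert top["mass"].tolist() == [0.5]
        assert len(rest) == 3

    def test_single_arc_plan(self):
        plan = self._shifted_plan([1.0])
        for frac in (0.01, 0.5, 0.99):
            top, rest = top_mass_arcs(plan, frac)
            assert len(top) == 1 and len(rest) == 0

    def test_equal_masses_tie_break(self):
        plan = self._shifted_plan(np.full(10, 0.1))
        top, rest = top_mass_arcs(plan, fraction=0.10)
        assert len(top) == 1
        assert top["i"].iloc[0] == plan.i[np.lexsort((plan.j, plan.i))[0]]

    def test_zero_cost_plan_empty_sets(self, rng):
        P = random_profile(rng)
        plan = solve_transport(P, P, depth_distance_matrix(P.axis, P.axis))
        top, rest = top_mass_arcs(plan)
        assert len(top) == 0 and len(rest) == 0
        assert len(transport_summary(plan)) == 0

    def test_summary_single_arc(self):
        P = ProbabilityField([1.0], axis=DepthAxis([96.0]))
        Q = ProbabilityField([1.0], axis=DepthAxis([140.0]))
        plan = solve_transport(P, Q, depth_distance_matrix(P.axis, Q.axis))
        tab = transport_summary(plan)
        assert len(tab) == 1
        assert tab["arc_m"].iloc[0] == 44.0 and tab["mass"].iloc[0] == 1.0

    def test_pooled_doubles_masses(self):
        plan = self._shifted_plan([0.4, 0.6])
        pooled = pooled_transport_summary([plan, plan])
        single = transport_summary(plan)
        assert pooled["mass"].sum() == pytest.approx(2 * single["mass"].sum())
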