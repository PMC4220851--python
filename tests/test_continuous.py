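import math

import numpy as np
import pytest

from kstoich import (FeasibilityError, ModelParams, free_potassium, quota,
                     recruitment_efficiency, rhs, scale, simulate,
                     tumour_growth_factor, unscale)
from kstoich.continuous import potassium_pools, rates_and_partials

from conftest import random_feasible_states


class TestQuota:
    def test_qss_closed_form(self, table1):
        # (q*mu_m/alpha + K_t) / (mu_m/alpha + x) at (1, 0)
        assert quota(1.0, 0.0, table1, "qss") == pytest.approx(0.0227286, abs=1e-7)

    def test_lke_is_pool_over_tumour(self, table1):
        assert quota(1.0, 0.0, table1, "lke") == pytest.approx(0.025)

    def test_lke_at_zero_tumour_is_infinite(self, table1):
        assert math.isinf(quota(0.0, 0.5, table1, "lke"))

    def test_qss_tends_to_lke_for_fast_uptake(self, table1):
        fast = table1.replace(alpha=1e9)
        assert quota(1.0, 0.0, fast, "qss") == pytest.approx(
            quota(1.0, 0.0, table1, "lke"), rel=1e-6)

    def test_qss_to_lke_sup_error_on_grid(self, table1):
        """alpha -> infinity collapses the qss closure onto lke pointwise."""
        fast = table1.replace(alpha=1e9)
        xs = np.linspace(0.05, 2.0, 40)
        ys = np.linspace(0.0, 0.8 * table1.K_t / table1.theta, 20)
        err = max(abs(quota(x, y, fast, "qss") - quota(x, y, table1, "lke"))
                  for x in xs for y in ys)
        assert err < 1e-6


class TestGrowthFactor:
    def test_potassium_limited_at_vanishing_tumour(self, table1):
        # Q(0,0) = q + (alpha/mu_m)*K_t ~ 0.212133; factor = b*(1 - q/Q)
        assert quota(0.0, 0.0, table1, "qss") == pytest.approx(0.212133, abs=1e-6)
        assert tumour_growth_factor(1e-15, 0.0, table1) == pytest.approx(
            1.17851, abs=1e-5)

    def test_zero_at_carbon_carrying_capacity(self, table1):
        p = table1.replace(K_t=0.5)  # potassium abundant: carbon branch binds
        assert tumour_growth_factor(p.L, 0.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_potassium_branch_root_at_Kt_over_q(self, table1):
        p = table1.replace(L=8.0)
        x_root = p.K_t / p.q
        assert x_root == pytest.approx(6.5789, abs=1e-3)
        for closure in ("qss", "lke"):
            assert tumour_growth_factor(x_root, 0.0, p, closure) == pytest.approx(
                0.0, abs=1e-12)

    def test_infeasible_state_raises(self, table1):
        with pytest.raises(FeasibilityError):
            tumour_growth_factor(0.5, table1.K_t / table1.theta + 0.1, table1)


class TestRecruitmentEfficiency:
    def test_saturates_at_e_when_potassium_rich(self, table1):
        assert recruitment_efficiency(0.1, 0.1, table1, "lke") == pytest.approx(0.8)

    def test_reduced_in_poor_regime(self, table1):
        # lke, (0.5, 0.7): Q = 0.004/0.5 = 0.008 < theta
        assert recruitment_efficiency(0.5, 0.7, table1, "lke") == pytest.approx(
            0.21333, abs=1e-5)

    def test_continuous_at_quota_switch(self, table1):
        # find y with Q(x, y) = theta at x = 0.5 (lke): K_t - theta*y = theta*x
        y_star = (table1.K_t - table1.theta * 0.5) / table1.theta
        below = recruitment_efficiency(0.5, y_star - 1e-9, table1, "lke")
        above = recruitment_efficiency(0.5, y_star + 1e-9, table1, "lke")
        assert below == pytest.approx(above, abs=1e-6)
        assert below == pytest.approx(table1.e, abs=1e-6)


class TestRhs:
    def test_boundary_equilibrium_is_fixed(self, table1):
        p = table1.replace(u=0.05)
        assert rhs(0.0, p.u / p.d, p) == pytest.approx((0.0, 0.0), abs=1e-15)

    def test_tumour_free_axis_dynamics(self, table1):
        p = table1.replace(u=0.05)
        for y in (0.05, 0.3, 0.7):
            dx, dy = rhs(0.0, y, p)
            assert dx == 0.0
            assert dy == pytest.approx(p.u - p.d * y)

    def test_khe_boundary_fixed_point(self, table1):
        p = table1.replace(L=8.0)  # k = K_t/q < L
        k = p.K_t / p.q
        assert rhs(k, 0.0, p) == pytest.approx((0.0, 0.0), abs=1e-14)
        assert rhs(min(table1.L, table1.K_t / table1.q), 0.0, table1) == \
            pytest.approx((0.0, 0.0), abs=1e-14)

    def test_gauge_invariance_of_theta(self, table1, rng):
        """The scaled model (p, s) determines the dynamics: rebuilding the
        parameters with any theta' gives an identical vector field."""
        base = table1.replace(l=0.2, u=0.05, K_t=0.045)
        sp = scale(base)
        states = random_feasible_states(base, 50, rng)
        for theta_prime in (0.01, 1.0, 2.7):
            other = unscale(sp, theta_prime)
            other = other.replace()  # frozen dataclass copy
            for x, y in states:
                if other.theta * y >= other.K_t:
                    continue
                got = rhs(x, y, other)
                want = rhs(x, y, base)
                assert got[0] == pytest.approx(want[0], rel=1e-12, abs=1e-14)
                assert got[1] == pytest.approx(want[1], rel=1e-12, abs=1e-14)

    def test_khe_reduction_matches_oracle(self, table1, rng):
        from khe_oracle import khe_rhs

        kw = {k: v for k, v in table1.to_dict().items() if k not in ("l", "u")}
        for closure in ("qss", "lke"):
            for x, y in random_feasible_states(table1, 500, rng):
                want = khe_rhs(x, y, closure=closure, **kw)
                got = rhs(x, y, table1, closure)
                assert got[0] == pytest.approx(want[0], rel=1e-12, abs=1e-15)
                assert got[1] == pytest.approx(want[1], rel=1e-12, abs=1e-15)


class TestPotassiumBookkeeping:
    def test_pools_sum_to_total(self, table1, rng):
        for closure in ("qss", "lke"):
            for x, y in random_feasible_states(table1, 100, rng):
                pools = potassium_pools(x, y, table1, closure)
                assert pools["K_c"] + pools["K_i"] + pools["K_f"] == pytest.approx(
                    table1.K_t, rel=1e-12)

    def test_free_pool_sign_matches_trapezoid_constraint(self, table1, rng):
        """Under qss, K_f >= 0 iff q*x + theta*y <= K_t (iff s*x + y <= p)."""
        xs = rng.uniform(0, 3 * table1.K_t / table1.q, 300)
        ys = rng.uniform(0, 0.99 * table1.K_t / table1.theta, 300)
        for x, y in zip(xs, ys):
            kf = free_potassium(x, y, table1, "qss")
            slack = table1.K_t - table1.theta * y - table1.q * x
            assert math.copysign(1, kf) == math.copysign(1, slack) or \
                abs(kf) < 1e-15


class TestSimulate:
    def test_holds_boundary_equilibrium(self, table1):
        p = table1.replace(u=0.05)
        traj = simulate((0.0, 0.2), 200.0, p)
        assert np.allclose(traj.x, 0.0, atol=1e-8)
        assert np.allclose(traj.y, 0.2, atol=1e-7)

    def test_stays_in_trapezoid(self, fig1_params):
        p = fig1_params
        sp = scale(p)
        traj = simulate((0.3, 0.3), 500.0, p)
        assert np.all(sp.s * traj.x + traj.y < sp.p + 1e-9)
        assert np.all(traj.x < min(p.L, sp.p / sp.s) + 1e-9)
        assert np.all(traj.x > -1e-9) and np.all(traj.y > 0)

    def test_quota_respects_floor_along_trajectory(self, fig1_params):
        traj = simulate((0.3, 0.3), 300.0, fig1_params)
        assert np.all(traj.Q >= fig1_params.q - 1e-12)

    def test_switch_crossings_are_logged(self, fig1_params):
        traj = simulate((0.3, 0.3), 300.0, fig1_params)
        # the oscillatory regime alternates carbon/potassium limitation
        assert len(set(traj.limiting_branch)) == 2
        assert any(c["surface"] == "liebig" for c in traj.switch_crossings)

    def test_infeasible_start_rejected(self, table1):
        with pytest.raises(FeasibilityError):
            simulate((0.1, table1.K_t / table1.theta), 10.0, table1)

    def test_rates_flag_switch_surface(self, table1):
        # on the Liebig switch carbon == potassium branch
        p = table1.replace(K_t=0.5)
        r = rates_and_partials(0.0, 0.0, p)
        assert r.limiting_branch in ("carbon", "potassium")
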