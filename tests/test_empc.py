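"""Tests for the economic MPC: stage costs, QP assembly, solver optimality."""

import numpy as np
import pytest

from aerompc import (ControllerConfig, build_qp, cost_eco, cost_slack,
                     cost_smooth, solve_step)
from aerompc.empc import shift_warm_start
from aerompc.model import InfluentRecord
from aerompc.params import PlantParameters
from aerompc.qlpv import build_matrices, discretize, scheduling_vector


@pytest.fixture
def op_point():
    """Operating-point state, influent and discretized prediction model."""
    p = PlantParameters()
    x0 = np.array([1.0, 2.0, 0.3, 15.0, 4500.0, 150.0])
    rec = InfluentRecord(t=0.0, Qin=7500.0, XCOD_in=500.0, SNH_in=35.0,
                         XBH_in=30.0)
    mats = discretize(build_matrices(scheduling_vector(x0, rec, p), p),
                      1.0 / 96)
    return p, x0, rec, mats


class TestStageCosts:
    def test_energy_formula_worked_example(self):
        """SO_sat=8, V_o=1800, KLa=10 -> 8/1800*1800*10 = 80 kWh/day."""
        p = PlantParameters(V_o=1800.0)
        assert cost_eco(10.0, p) == pytest.approx(80.0)

    def test_energy_linearity(self, params):
        assert cost_eco(0.0, params) == 0.0
        assert cost_eco(40.0, params) == pytest.approx(2 * cost_eco(20.0,
                                                                    params))
        with pytest.raises(ValueError):
            cost_eco(-1.0, params)

    def test_slack_cost_is_squared_two_norm(self):
        assert cost_slack([0.0], [0.0]) == 0.0
        assert cost_slack([1.0], [2.0]) == pytest.approx(5.0)
        assert cost_slack([1.0, 2.0], [0.5]) == pytest.approx(
            cost_slack([2.0, 1.0], [0.5]))
        with pytest.raises(ValueError):
            cost_slack([-0.1], [0.0])

    def test_smoothing_cost_quadratic_scaling(self):
        assert cost_smooth(0.0, 1.0) == 0.0
        assert cost_smooth(2.0, 1.0) == pytest.approx(4.0)
        assert cost_smooth(3.0, 0.5) == pytest.approx(
            9.0 * cost_smooth(1.0, 0.5))


class TestQPAssembly:
    def test_convexity_of_quadratic_term(self, op_point):
        p, x0, rec, mats = op_point
        cfg = ControllerConfig()
        qp = build_qp(x0, mats, np.tile(rec.exogenous(), (cfg.Hp, 1)),
                      120.0, cfg, p)
        H = qp.quadratic_term()
        np.testing.assert_allclose(H, H.T, atol=1e-12)
        assert np.linalg.eigvalsh(H).min() >= -1e-10

    def test_objective_gradient_matches_finite_differences(self, op_point):
        p, x0, rec, mats = op_point
        cfg = ControllerConfig(Hp=6)
        qp = build_qp(x0, mats, np.tile(rec.exogenous(), (cfg.Hp, 1)),
                      120.0, cfg, p)
        rng = np.random.default_rng(2)
        u = rng.uniform(50.0, 200.0, cfg.Hp)
        f0, g = qp.objective(u)
        for j in range(cfg.Hp):
            e = np.zeros(cfg.Hp)
            e[j] = 1e-4
            fp, _ = qp.objective(u + e)
            fm, _ = qp.objective(u - e)
            assert (fp - fm) / 2e-4 == pytest.approx(g[j], rel=1e-4,
                                                     abs=1e-3)

    def test_forecast_shape_checked(self, op_point):
        p, x0, rec, mats = op_point
        cfg = ControllerConfig(Hp=4)
        with pytest.raises(ValueError, match="shape"):
            build_qp(x0, mats, np.zeros((3, 3)), 100.0, cfg, p)
        with pytest.raises(ValueError, match="finite"):
            build_qp(x0, mats, np.full((4, 3), np.nan), 100.0, cfg, p)

    def test_undiscretized_matrices_rejected(self, op_point):
        p, x0, rec, _ = op_point
        raw = build_matrices(scheduling_vector(x0, rec, p), p)
        with pytest.raises(ValueError, match="discretized"):
            build_qp(x0, raw, np.zeros((24, 3)), 100.0, ControllerConfig(), p)


class TestSolverOptimality:
    def test_horizon_one_closed_form(self, op_point):
        """Unconstrained stationary point of w1*c*u + w2*Wu*(u-u_prev)^2.

        With a wide-open DO band and state box, the optimum is
        u_prev - w1*c/(2*w2*Wu), clipped to the input box.
        """
        p, x0, rec, mats = op_point
        u_prev = 150.0
        cfg = ControllerConfig(Hp=1, w1=1.0, w2=1.0, w3=1e4, Wu=2.0,
                               DO_band_low=0.01, DO_band_high=50.0,
                               band_margin=0.0,
                               x_max=(1e5,) * 6, y_max=(1e5,) * 3)
        qp = build_qp(x0, mats, np.tile(rec.exogenous(), (1, 1)), u_prev,
                      cfg, p)
        sol = solve_step(qp)
        c = p.SO_sat / 1800.0 * p.V_o
        expected = np.clip(u_prev - cfg.w1 * c / (2 * cfg.w2 * cfg.Wu),
                           cfg.u_min, cfg.u_max)
        assert sol.status == "solved"
        assert sol.u_seq[0] == pytest.approx(expected, abs=1e-2)

    def test_horizon_two_against_grid_search(self, op_point):
        """Solver optimum matches a brute-force grid oracle at Hp=2."""
        p, x0, rec, mats = op_point
        cfg = ControllerConfig(Hp=2, Wu=2.0)
        qp = build_qp(x0, mats, np.tile(rec.exogenous(), (2, 1)), 120.0,
                      cfg, p)
        sol = solve_step(qp)

        def grid_min(r0, r1, step):
            g0 = np.arange(r0[0], r0[1] + step / 2, step)
            g1 = np.arange(r1[0], r1[1] + step / 2, step)
            best, best_u = np.inf, None
            for u0 in g0:
                for u1 in g1:
                    f, _ = qp.objective(np.array([u0, u1]))
                    if f < best:
                        best, best_u = f, (u0, u1)
            return best, np.array(best_u)

        # coarse pass over the admissible square, then a 0.01-resolution
        # refinement around each coarse coordinate
        full = (cfg.u_min, cfg.u_max)
        f_c, u_c = grid_min(full, full, 2.0)
        refine = [(max(cfg.u_min, c - 2.5), min(cfg.u_max, c + 2.5))
                  for c in u_c]
        f_f, u_f = grid_min(refine[0], refine[1], 0.01)
        assert sol.J_total <= f_f + 1e-6
        f_sol, _ = qp.objective(sol.u_seq)
        assert f_sol == pytest.approx(f_f, abs=max(1e-4 * abs(f_f), 1e-2))

    def test_zero_slack_when_band_strictly_satisfiable(self, op_point):
        """With no economic pressure and the trajectory inside a wide
        band, the optimal slacks are exactly zero."""
        p, x0, rec, mats = op_point
        cfg = ControllerConfig(DO_band_low=0.3, DO_band_high=7.0,
                               band_margin=0.0, w1=0.0, w3=1e6)
        qp = build_qp(x0, mats, np.tile(rec.exogenous(), (cfg.Hp, 1)),
                      140.0, cfg, p)
        sol = solve_step(qp)
        assert sol.status == "solved"
        assert np.all(sol.lambda_minus == 0.0)
        assert np.all(sol.lambda_plus == 0.0)
        assert sol.J_lambda == 0.0

    def test_resolve_is_deterministic(self, op_point):
        p, x0, rec, mats = op_point
        cfg = ControllerConfig()
        w = np.tile(rec.exogenous(), (cfg.Hp, 1))
        qp1 = build_qp(x0, mats, w, 120.0, cfg, p)
        qp2 = build_qp(x0, mats, w, 120.0, cfg, p)
        s1, s2 = solve_step(qp1), solve_step(qp2)
        np.testing.assert_array_equal(s1.u_seq, s2.u_seq)

    def test_objective_decomposition_consistent(self, op_point):
        p, x0, rec, mats = op_point
        cfg = ControllerConfig()
        qp = build_qp(x0, mats, np.tile(rec.exogenous(), (cfg.Hp, 1)),
                      120.0, cfg, p)
        sol = solve_step(qp)
        assert sol.J_total == pytest.approx(
            cfg.w1 * sol.J_eco + cfg.w2 * sol.J_smo
            + cfg.w3 * sol.J_lambda + sol.J_box, rel=1e-9)
        assert cfg.u_min <= sol.u_seq.min() <= sol.u_seq.max() <= cfg.u_max

    def test_one_step_prediction_consistency_on_linear_plant(self, op_point):
        """No plant-model mismatch: realized next state equals prediction."""
        p, x0, rec, mats = op_point
        cfg = ControllerConfig()
        w = rec.exogenous()
        qp = build_qp(x0, mats, np.tile(w, (cfg.Hp, 1)), 120.0, cfg, p)
        sol = solve_step(qp)
        x_next = mats.Ad @ x0 + mats.Bd[:, 0] * sol.u_seq[0] + mats.Ed @ w
        np.testing.assert_allclose(sol.x_pred[0], x_next, rtol=1e-10)

    def test_band_recovery_when_energy_ignored(self, op_point):
        """w1=0, DO below band: the controller drives DO back up fast."""
        from aerompc import PlantState, integrate
        p, _, rec, _ = op_point
        x = np.array([1.0, 0.8, 0.3, 15.0, 4500.0, 150.0])  # DO below 1.5
        cfg = ControllerConfig(w1=0.0, w3=1e4)
        u_prev, warm = 100.0, None
        from aerompc.qlpv import discretize_along
        for k in range(4):
            mats = discretize_along(x, rec, u_prev, cfg.h, 20, p)
            qp = build_qp(x, mats, np.tile(rec.exogenous(), (cfg.Hp, 1)),
                          u_prev, cfg, p)
            sol = solve_step(qp, warm)
            u = float(sol.u_seq[0])
            _, X = integrate(PlantState.from_array(x), lambda t: rec,
                             lambda t: u, (0.0, cfg.h), p)
            x = X[-1]
            u_prev, warm = u, shift_warm_start(sol)
        assert x[1] >= cfg.DO_band_low

    def test_warm_start_shift(self, op_point):
        p, x0, rec, mats = op_point
        cfg = ControllerConfig(Hp=4)
        qp = build_qp(x0, mats, np.tile(rec.exogenous(), (4, 1)), 120.0,
                      cfg, p)
        sol = solve_step(qp)
        shifted = shift_warm_start(sol)
        np.testing.assert_array_equal(shifted[:-1], sol.u_seq[1:])
        assert shifted[-1] == sol.u_seq[-1]


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"Hp": 0}, {"w1": -1.0}, {"DO_band_low": 3.0, "DO_band_high": 2.0},
        {"u_min": 240.0, "u_max": 240.0}, {"band_margin": 2.0},
    ])
    def test_invalid_controller_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ControllerConfig(**kwargs)
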