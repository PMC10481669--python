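"""Unit tests for the osmotic/Darcy pressure model."""
from __future__ import annotations

import numpy as np
import pytest

import biliflow as bf
from biliflow.config import UM
from biliflow.pressure import (
    osmolyte_balance_residual,
    water_balance_residual,
)
from biliflow.types import RadialGeometry

from conftest import make_params


def flat_geometry(n=401, rho0_um=50.0, L_um=512.0, eps=0.1, r_um=0.5, f=0.28,
                  tau=1.8):
    rho = np.linspace(rho0_um, L_um, n) * UM
    r = r_um * UM
    return RadialGeometry(
        rho=rho,
        apical_density=np.full(n, 2.0 * eps / r),
        eps_bc=np.full(n, eps),
        r_bc=np.full(n, r),
        f=np.full(n, f),
        tau=tau,
    )


class TestDarcyResistance:
    def test_hand_evaluated_value(self):
        # 8 * 9.2e-4 * 1.8^2 / (0.1 * (0.5e-6)^2 * 0.28) Pa s / m^2
        geom = flat_geometry()
        K = bf.darcy_resistance(geom, mu=9.2e-4)
        assert K == pytest.approx(3.40662857142857e12, rel=1e-12)

    def test_doubling_f_halves_K(self):
        geom = flat_geometry()
        geom2 = flat_geometry(f=0.56)
        np.testing.assert_allclose(
            bf.darcy_resistance(geom, 9.2e-4),
            2.0 * bf.darcy_resistance(geom2, 9.2e-4),
            rtol=1e-14,
        )

    def test_tau_squared_scaling(self):
        k1 = bf.darcy_resistance(flat_geometry(tau=1.0), 9.2e-4)
        k2 = bf.darcy_resistance(flat_geometry(tau=2.0), 9.2e-4)
        np.testing.assert_allclose(k2, 4.0 * k1, rtol=1e-14)

    def test_rejects_bad_viscosity(self):
        with pytest.raises(ValueError, match="mu"):
            bf.darcy_resistance(flat_geometry(), 0.0)


class TestOsmolyteInflux:
    def test_zero_secretion(self):
        geom = flat_geometry()
        assert np.all(bf.osmolyte_influx(geom, 0.0) == 0.0)

    def test_constant_secretion_closed_form(self):
        geom = flat_geometry(n=2001)
        g = 1.7
        G = bf.osmolyte_influx(geom, g)
        exact = g * (geom.rho**2 - geom.rho0**2) / 2.0
        np.testing.assert_allclose(G[1:], exact[1:], rtol=1e-6)
        assert G[0] == 0.0

    def test_localized_bump_plateaus(self):
        geom = flat_geometry(n=1001)
        g = np.zeros_like(geom.rho)
        sel = (geom.rho > 1.5e-4) & (geom.rho < 2.5e-4)
        g[sel] = 3.0
        G = bf.osmolyte_influx(geom, g)
        before = geom.rho <= 1.4e-4
        after = geom.rho >= 2.6e-4
        assert np.all(G[before] == 0.0)
        assert np.allclose(G[after], G[-1], rtol=1e-12)
        # cross-check against an independent trapezoid on the same grid
        oracle = np.concatenate(
            [[0.0], np.cumsum(0.5 * ((geom.rho * g)[1:] + (geom.rho * g)[:-1])
                              * np.diff(geom.rho))]
        )
        np.testing.assert_allclose(G, oracle, rtol=1e-12, atol=1e-30)

    def test_length_mismatch_rejected(self):
        geom = flat_geometry(n=10)
        with pytest.raises(ValueError, match="length"):
            bf.osmolyte_influx(geom, np.ones(7))


class TestCentralStartState:
    def test_quadratic_root_residual(self):
        geom = flat_geometry()
        params = make_params(g=1.0)
        u, p, c_star = bf.central_start_state(1500.0, geom, params)
        kA = params.kappa * geom.apical_density[0]
        residual = (
            kA * params.RT * c_star**2
            - kA * (params.RT * params.c0 + 1500.0) * c_star
            - 1.0
        )
        scale = kA * params.RT * c_star**2
        assert abs(residual) / scale < 1e-10

    def test_c_star_monotone_in_g(self):
        geom = flat_geometry()
        cs = [
            bf.central_start_state(1000.0, geom, make_params(g=g))[2]
            for g in (0.01, 0.1, 1.0, 10.0, 100.0)
        ]
        assert np.all(np.diff(cs) > 0)

    def test_u_vanishes_with_delta(self):
        geom = flat_geometry()
        params = make_params(g=1.0)
        u1 = bf.central_start_state(1000.0, geom, params, delta=1e-8)[0]
        u2 = bf.central_start_state(1000.0, geom, params, delta=1e-10)[0]
        # u is linear in the offset, so it vanishes in the delta -> 0 limit
        assert u2 == pytest.approx(u1 * 1e-2, rel=1e-9)

    def test_degenerate_secretion_falls_back(self):
        geom = flat_geometry()
        params = make_params(g=0.0, p_duct=1000.0)
        # g = 0 with p0 <= -RT c0 has no positive root
        with pytest.warns(RuntimeWarning, match="no positive root"):
            _, _, c_star = bf.central_start_state(
                -2.0 * params.RT * params.c0, geom, params
            )
        assert c_star > 0


class TestIntegrateOutward:
    def test_impermeable_limit(self):
        geom = flat_geometry()
        traj = bf.integrate_outward(1234.0, geom, make_params(g=1.0, kappa=0.0))
        assert np.all(traj.u == 0.0)
        assert np.all(traj.p == 1234.0)

    def test_osmolyte_conservation_along_trajectory(self):
        geom = flat_geometry(n=801)
        params = make_params(g=1.0)
        traj = bf.integrate_outward(2000.0, geom, params)
        G = bf.osmolyte_influx(geom, params.g_profile(geom))
        sel = geom.rho > geom.rho0 + traj.delta
        c = G[sel] / traj.u[sel]
        np.testing.assert_allclose(traj.u[sel] * c, G[sel], rtol=1e-6)

    def test_tolerance_convergence(self):
        geom = flat_geometry(n=801)
        params = make_params(g=1.0)
        p_coarse = bf.integrate_outward(2000.0, geom, params, rtol=1e-6).p[-1]
        p_fine = bf.integrate_outward(2000.0, geom, params, rtol=1e-10).p[-1]
        # halving (here: sharply tightening) the tolerance moves the terminal
        # pressure by far less than the coarse solution's own error budget
        assert abs(p_coarse - p_fine) < 1.0


class TestSolvePressure:
    def test_impermeable_limit_returns_duct_pressure(self):
        geom = flat_geometry()
        sol = bf.solve_pressure(geom, make_params(g=1.0, kappa=0.0, p_duct=900.0))
        assert np.all(sol.p == 900.0)
        assert np.all(sol.w == 0.0)
        assert sol.residual == 0.0

    def test_pressure_decreases_outward(self, control_geometry):
        sol = bf.solve_pressure(control_geometry, make_params(g=1.0))
        assert sol.p[0] > sol.p[-1]
        assert np.all(np.diff(sol.p) <= 0)
        assert sol.w[0] == 0.0
        assert abs(sol.p[-1] - 1000.0) <= 0.1

    def test_conservation_residuals(self, control_geometry):
        params = make_params(g=1.0)
        sol = bf.solve_pressure(control_geometry, params)
        assert water_balance_residual(sol, control_geometry, params) < 1e-5
        assert osmolyte_balance_residual(sol, control_geometry, params) < 1e-5

    def test_hint_does_not_change_answer(self, control_geometry):
        params = make_params(g=1.0)
        a = bf.solve_pressure(control_geometry, params)
        b = bf.solve_pressure(control_geometry, params, p0_hint=a.p0)
        assert b.p0 == pytest.approx(a.p0, abs=0.1)


class TestCanalicularVelocity:
    def test_identity_and_scaling(self, control_geometry):
        sol = bf.solve_pressure(control_geometry, make_params(g=1.0))
        wc = bf.canalicular_velocity(sol, control_geometry)
        np.testing.assert_allclose(
            wc * control_geometry.eps_bc, sol.w, rtol=1e-14, atol=1e-300
        )
        flat = flat_geometry(eps=0.5, n=control_geometry.rho.size,
                             rho0_um=50.0, L_um=512.0)
        sol2 = bf.solve_pressure(flat, make_params(g=1.0))
        np.testing.assert_allclose(
            bf.canalicular_velocity(sol2, flat), 2.0 * sol2.w, rtol=1e-14
        )


class TestZonePressureSummary:
    @staticmethod
    def _fake_solution(rho, p):
        z = np.zeros_like(rho)
        return bf.PressureSolution(
            rho=rho, w=z, p=p, c=z, wc=z, G=z, K=z, p0=float(p[0]),
            residual=0.0, iterations=0,
        )

    def test_constant_profile(self):
        rho = np.linspace(1.0, 2.0, 241)
        s = bf.zone_pressure_summary(
            self._fake_solution(rho, np.full_like(rho, 1000.0))
        )
        assert np.all(s.zone_medians == 1000.0)
        assert s.elevation == 0.0
        assert s.axis_median == 1000.0

    def test_strictly_decreasing_profile(self):
        rho = np.linspace(1.0, 2.0, 241)
        s = bf.zone_pressure_summary(self._fake_solution(rho, 3000.0 - 500.0 * rho))
        assert np.all(np.diff(s.zone_medians) < 0)
        assert s.elevation > 0

    def test_linear_profile_elevation_matches_brute_force(self):
        rho = np.linspace(1.0, 2.0, 2201)
        p = 2000.0 - 1000.0 * (rho - 1.0)
        s = bf.zone_pressure_summary(self._fake_solution(rho, p), n_zones=11)
        # independent brute force on the discretized profile
        t = (rho - rho[0]) / (rho[-1] - rho[0])
        zones = np.minimum((t * 11).astype(int), 10)
        medians = np.array([np.median(p[zones == z]) for z in range(11)])
        np.testing.assert_allclose(s.zone_medians, medians, rtol=0, atol=0)
        assert s.elevation == pytest.approx(medians[0] - medians[-1])
        # midpoint medians put the elevation at ~ 1000 * 10/11
        assert s.elevation == pytest.approx(1000.0 * 10.0 / 11.0, rel=0.01)

    def test_empty_zone_rejected(self):
        rho = np.linspace(1.0, 2.0, 5)
        with pytest.raises(ValueError, match="zone"):
            bf.zone_pressure_summary(
                self._fake_solution(rho, np.full_like(rho, 1.0)), n_zones=11
            )


class TestCalibrateSecretion:
    def test_degenerate_target_at_duct_pressure(self, control_geometry):
        params = make_params(g=0.0, kappa=0.0)
        g = bf.calibrate_secretion(control_geometry, params, 1000.0)
        assert g == 0.0

    def test_target_below_duct_pressure_rejected(self, control_geometry):
        with pytest.raises(ValueError, match="below"):
            bf.calibrate_secretion(control_geometry, make_params(), 900.0)

    def test_monotone_in_target(self, control_geometry):
        params = make_params(g=0.0)
        g1 = bf.calibrate_secretion(control_geometry, params, 1500.0)
        g2 = bf.calibrate_secretion(control_geometry, params, 2500.0)
        assert 0 < g1 < g2
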