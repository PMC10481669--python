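"""Osmotic/Darcy canalicular bile-pressure model on the lobule annulus.

The lobule is a radially symmetric cylinder of radius L with the central vein
(radius rho0) on its axis. Water enters the canalicular lumen osmotically
across the apical membrane and drains outward through the canalicular network,
treated as a porous medium. In terms of the radial bulk velocity w, pressure p
and osmolyte concentration c, mass conservation and Darcy's law give

    (rho w)'/rho = kappa A (RT (c - c0) - p)
    (rho c w)'/rho = g
    p' = -K(rho) w

with boundary conditions w(rho0) = 0 and p(L) = p_duct, where the flow
resistance follows from porous-media theory,

    K(rho) = 8 mu tau^2 / (eps_BC(rho) r_BC(rho)^2 f(rho)).

The concentration equation integrates to rho c w = G(rho) with
G = int_{rho0}^{rho} rho~ g(rho~) d rho~, so eliminating c leaves a two-state
system in u = rho w and p that is singular at the central vein (c = G/u is
0/0 there). We start the integration a small offset delta off the axis using
the analytic limit of c (a quadratic fixed point, see
:func:`central_start_state`) and solve the terminal condition p(L) = p_duct
by shooting on the central pressure p0.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import brentq

from .config import N_ZONES
from .types import BileParams, PressureSolution, RadialGeometry

logger = logging.getLogger("biliflow.pressure")

__all__ = [
    "darcy_resistance",
    "osmolyte_influx",
    "central_start_state",
    "integrate_outward",
    "solve_pressure",
    "canalicular_velocity",
    "zone_pressure_summary",
    "calibrate_secretion",
    "water_balance_residual",
    "osmolyte_balance_residual",
    "ZonePressureSummary",
]


def darcy_resistance(geom: RadialGeometry, mu: float) -> np.ndarray:
    """Flow resistance K(rho) = 8 mu tau^2 / (eps_BC r_BC^2 f), Pa s/m^2."""
    if mu <= 0:
        raise ValueError("viscosity mu must be positive")
    denom = geom.eps_bc * geom.r_bc**2 * geom.f
    if np.any(denom <= 0):
        bad = int(np.flatnonzero(denom <= 0)[0])
        raise ValueError(
            f"non-positive eps_bc * r_bc^2 * f at grid point {bad} "
            f"(rho = {geom.rho[bad]:.6g} m)"
        )
    return 8.0 * mu * geom.tau**2 / denom


def osmolyte_influx(geom: RadialGeometry, g: float | np.ndarray) -> np.ndarray:
    """Cumulative osmolyte influx G(rho) = int_{rho0}^{rho} rho~ g d rho~.

    Trapezoid quadrature on the geometry grid; G(rho0) = 0 and G is
    non-decreasing for g >= 0.
    """
    garr = np.asarray(g, dtype=float)
    if garr.ndim == 0:
        garr = np.full(geom.rho.size, float(garr))
    if garr.size != geom.rho.size:
        raise ValueError(
            f"secretion profile length {garr.size} does not match grid "
            f"length {geom.rho.size}"
        )
    return cumulative_trapezoid(geom.rho * garr, geom.rho, initial=0.0)


def central_start_state(
    p0: float,
    geom: RadialGeometry,
    params: BileParams,
    delta: Optional[float] = None,
) -> tuple[float, float, float]:
    """Regularized state (u, p, c*) at rho0 + delta.

    At the central vein u = rho w vanishes while G vanishes too, so
    c = G/u is a 0/0 limit. Writing G ~ rho0 g delta and
    u ~ rho0 kappa A (RT (c* - c0) - p0) delta, self-consistency requires

        kappa A RT c*^2 - kappa A (RT c0 + p0) c* - g = 0,

    whose positive root is the limiting concentration. For g > 0 this root
    always exists and gives a positive osmotic driving force
    RT (c* - c0) - p0 = g / (kappa A c*).
    """
    if not np.isfinite(p0):
        raise ValueError("p0 must be finite")
    if delta is None:
        delta = 1e-3 * (geom.L - geom.rho0)
    A0 = float(geom.apical_density[0])
    g0 = float(np.asarray(params.g_profile(geom))[0])
    RT = params.RT
    kA = params.kappa * A0

    c_star = None
    if kA > 0:
        a = kA * RT
        b = -kA * (RT * params.c0 + p0)
        disc = b * b + 4.0 * a * g0
        root = (-b + np.sqrt(disc)) / (2.0 * a)
        if root > 0:
            c_star = float(root)
    if c_star is None:
        c_star = params.c0 * (1.0 + 1e-9)
        warnings.warn(
            "no positive root for the central concentration; falling back to "
            "c* = c0 (1 + 1e-9)",
            RuntimeWarning,
            stacklevel=2,
        )
    drive = RT * (c_star - params.c0) - p0
    u = geom.rho0 * kA * drive * delta
    return float(u), float(p0), c_star


@dataclass
class _Trajectory:
    rho: np.ndarray
    u: np.ndarray
    p: np.ndarray
    dense: Optional[object]
    c_star: float
    delta: float
    trivial: bool


def _profiles(geom: RadialGeometry, params: BileParams):
    rho = geom.rho
    A = geom.apical_density
    K = darcy_resistance(geom, params.mu)
    g = params.g_profile(geom)
    G = osmolyte_influx(geom, g)
    return rho, A, K, g, G


def integrate_outward(
    p0: float,
    geom: RadialGeometry,
    params: BileParams,
    rtol: float = 1e-8,
    start_offset_fraction: float = 1e-3,
    method: str = "LSODA",
) -> _Trajectory:
    """Integrate the eliminated system u' , p' from rho0 + delta to L.

    States are u = rho w and p with

        u' = rho kappa A (RT (G/u - c0) - p),    p' = -K u / rho.

    A stiff-capable adaptive integrator (LSODA) is used; profiles are linearly
    interpolated between grid points. The impermeable (kappa = 0) and
    secretion-free (G == 0) limits are returned analytically: u == 0 and
    p == p0.
    """
    rho, A, K, g, G = _profiles(geom, params)
    RT = params.RT

    if params.kappa == 0.0 or G[-1] <= 0.0:
        return _Trajectory(
            rho=rho,
            u=np.zeros_like(rho),
            p=np.full_like(rho, p0),
            dense=None,
            c_star=params.c0 + p0 / RT if params.c0 + p0 / RT > 0 else params.c0,
            delta=0.0,
            trivial=True,
        )

    delta = start_offset_fraction * (geom.L - geom.rho0)
    u0, pp0, c_star = central_start_state(p0, geom, params, delta)
    start = geom.rho0 + delta
    # refine the series start to be consistent with the quadrature grid: the
    # osmolyte balance u c = G at c = c* gives u(a) = G(a)/c*, which equals
    # the leading-order series up to O(delta^2) but avoids a spurious
    # concentration transient at the first integrator step. The 1e-6
    # off-manifold nudge makes the stiffness visible to LSODA's method
    # switching immediately (an exactly-on-manifold start can leave it in
    # non-stiff mode, where weakly driven cases crawl); its transient decays
    # within the first step and is far below the integration tolerance
    G_a = float(np.interp(start, rho, G))
    if G_a > 0 and c_star > 0:
        u0 = (G_a / c_star) * (1.0 - 1e-6)
    u_floor = max(abs(u0) * 1e-9, 1e-300)

    kappa, c0 = params.kappa, params.c0

    def rhs(r: float, y: np.ndarray) -> list[float]:
        u, p = y
        Ar = np.interp(r, rho, A)
        Kr = np.interp(r, rho, K)
        Gr = np.interp(r, rho, G)
        c = Gr / max(u, u_floor)
        du = r * kappa * Ar * (RT * (c - c0) - p)
        dp = -Kr * u / r
        return [du, dp]

    def jac(r: float, y: np.ndarray) -> list[list[float]]:
        u, p = y
        Ar = np.interp(r, rho, A)
        Kr = np.interp(r, rho, K)
        Gr = np.interp(r, rho, G)
        return [
            [-r * kappa * Ar * RT * Gr / max(u, u_floor) ** 2, -r * kappa * Ar],
            [-Kr / r, 0.0],
        ]

    sol = solve_ivp(
        rhs,
        (start, geom.L),
        [u0, pp0],
        method=method,
        rtol=rtol,
        atol=[max(abs(u0) * 1e-8, 1e-300), 1e-8],
        dense_output=True,
        jac=jac,
    )
    if not sol.success:
        raise RuntimeError(
            f"outward integration failed for p0 = {p0:.6g} Pa: {sol.message}"
        )

    inside = rho > start
    u_grid = np.empty_like(rho)
    p_grid = np.empty_like(rho)
    if np.any(inside):
        vals = sol.sol(rho[inside])
        u_grid[inside] = vals[0]
        p_grid[inside] = vals[1]
    # points at or inside the regularization offset take the series values
    u_grid[~inside] = u0 * (rho[~inside] - geom.rho0) / delta
    p_grid[~inside] = p0
    u_grid[0] = 0.0
    p_grid[0] = p0
    return _Trajectory(
        rho=rho, u=u_grid, p=p_grid, dense=sol.sol, c_star=c_star,
        delta=delta, trivial=False,
    )


def solve_pressure(
    geom: RadialGeometry,
    params: BileParams,
    tol: float = 0.1,
    rtol: float = 1e-8,
    start_offset_fraction: float = 1e-3,
    max_p0: float = 1e8,
    method: str = "LSODA",
    p0_hint: Optional[float] = None,
) -> PressureSolution:
    """Solve the boundary-value problem by shooting on the central pressure.

    The shooting residual r(p0) = p(L; p0) - p_duct is increasing in p0
    (raising the central pressure both raises the whole profile and throttles
    the osmotic influx, shrinking the Darcy drop), so a geometric bracket
    expansion upward from p_duct followed by Brent refinement is used.
    ``p0_hint`` (a central pressure from a comparable earlier solve) seeds
    the bracket and saves expansion steps; it never changes the answer.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    pL = params.p_duct
    n_eval = 0

    def residual(p0: float) -> float:
        nonlocal n_eval
        n_eval += 1
        traj = integrate_outward(
            p0, geom, params, rtol=rtol,
            start_offset_fraction=start_offset_fraction, method=method,
        )
        return traj.p[-1] - pL

    r_lo = residual(pL)
    if abs(r_lo) <= tol:
        p0 = pL
    else:
        if r_lo > 0:  # pressure rises outward: not expected with g >= 0
            raise RuntimeError(
                "shooting residual positive at p0 = p_duct; review parameters"
            )
        lo, hi = pL, None
        if p0_hint is not None and p0_hint > pL:
            h_lo = pL + 0.25 * (p0_hint - pL)
            h_hi = pL + 4.0 * (p0_hint - pL)
            r1 = residual(h_lo)
            if r1 < 0:
                r2 = residual(h_hi)
                if r2 >= 0:
                    lo, hi = h_lo, h_hi
                else:
                    lo = h_hi
            else:
                lo, hi = pL, h_lo
        if hi is None:
            step = max(100.0, 0.5 * abs(pL), lo - pL)
            hi = lo
            r_hi = -1.0
            while r_hi < 0:
                hi = hi + step
                step *= 2.0
                if hi > max_p0:
                    raise RuntimeError(
                        f"no shooting bracket below p0 = {max_p0:.3g} Pa; "
                        "review geometry and secretion parameters"
                    )
                r_hi = residual(hi)
        p0 = brentq(residual, lo, hi, xtol=0.25 * tol, rtol=8.9e-16)

    traj = integrate_outward(
        p0, geom, params, rtol=rtol,
        start_offset_fraction=start_offset_fraction, method=method,
    )
    resid = abs(traj.p[-1] - pL)
    if resid > tol:
        # |r| at the brentq root scales as slope * xtol and the slope can
        # exceed unity; polish with a tight bracket around the root
        r_here = traj.p[-1] - pL
        span = 4.0 * resid
        lo2, hi2 = (p0 - span, p0) if r_here > 0 else (p0, p0 + span)
        for _ in range(8):
            if residual(lo2) < 0 < residual(hi2):
                break
            span *= 4.0
            lo2, hi2 = p0 - span, p0 + span
        p0 = brentq(residual, lo2, hi2, xtol=0.02 * tol, rtol=8.9e-16)
        traj = integrate_outward(
            p0, geom, params, rtol=rtol,
            start_offset_fraction=start_offset_fraction, method=method,
        )
        resid = abs(traj.p[-1] - pL)
    if resid > tol:
        raise RuntimeError(
            f"shooting did not converge: terminal residual {resid:.3g} Pa "
            f"exceeds tolerance {tol:.3g} Pa (last p0 = {p0:.6g} Pa)"
        )

    rho, A, K, g, G = _profiles(geom, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(rho > 0, traj.u / rho, 0.0)
        c = np.where(traj.u > 0, G / np.maximum(traj.u, 1e-300), traj.c_star)
    w[0] = 0.0
    c[0] = traj.c_star
    if traj.trivial:
        c = np.full_like(rho, traj.c_star)
    wc = w / geom.eps_bc
    return PressureSolution(
        rho=rho, w=w, p=traj.p, c=c, wc=wc, G=G, K=K,
        p0=float(p0), residual=float(resid), iterations=n_eval,
        dense=traj.dense, start_offset=traj.delta,
    )


def canalicular_velocity(sol: PressureSolution, geom: RadialGeometry) -> np.ndarray:
    """Canaliculus velocity wc = w / eps_BC, pointwise on the grid."""
    if np.any(geom.eps_bc == 0):
        raise ValueError("eps_bc vanishes somewhere; wc undefined")
    if sol.w.size != geom.eps_bc.size:
        raise ValueError("solution and geometry grids differ")
    return sol.w / geom.eps_bc


# ---------------------------------------------------------------------------
# zone summaries and calibration
# ---------------------------------------------------------------------------

@dataclass
class ZonePressureSummary:
    """Median pressures per CV-PV zone (0 pericentral .. n-1 periportal)."""

    zone_medians: np.ndarray  # Pa, length n_zones
    axis_median: float  # median of the pointwise pressure profile (canonical)
    axis_median_of_zones: float  # median over zone medians (also reported)
    elevation: float  # zone-0 median minus last-zone median, Pa
    n_zones: int


def _zone_bins(x: np.ndarray, lo: float, hi: float, n_zones: int) -> np.ndarray:
    t = (x - lo) / (hi - lo)
    return np.minimum((t * n_zones).astype(int), n_zones - 1)


def zone_pressure_summary(
    sol: PressureSolution, n_zones: int = N_ZONES
) -> ZonePressureSummary:
    """Partition the axis into equal-width zones and take per-zone medians."""
    if n_zones < 2:
        raise ValueError("need at least 2 zones")
    zones = _zone_bins(sol.rho, sol.rho[0], sol.rho[-1], n_zones)
    medians = np.empty(n_zones)
    for z in range(n_zones):
        sel = zones == z
        if not np.any(sel):
            raise ValueError(f"zone {z} holds no grid points; grid too coarse")
        medians[z] = np.median(sol.p[sel])
    return ZonePressureSummary(
        zone_medians=medians,
        axis_median=float(np.median(sol.p)),
        axis_median_of_zones=float(np.median(medians)),
        elevation=float(medians[0] - medians[-1]),
        n_zones=n_zones,
    )


def calibrate_secretion(
    geom: RadialGeometry,
    params: BileParams,
    target_axis_median: float,
    rel_tol: float = 1e-3,
    g_max: float = 1e3,
    n_zones: int = N_ZONES,
    solver_tol: float = 0.1,
    rtol: float = 1e-8,
    method: str = "LSODA",
) -> float:
    """Constant secretion rate g reproducing a target axis-median pressure.

    The axis median is increasing in g (more osmolytes draw more water, and
    the larger Darcy drop raises the whole profile above the fixed portal
    boundary), so a bracketed root find on g suffices. The target must lie at
    or above the portal pressure p_duct.
    """
    pL = params.p_duct
    if target_axis_median < pL:
        raise ValueError(
            f"target {target_axis_median:.6g} Pa lies below the portal "
            f"boundary pressure {pL:.6g} Pa"
        )

    last_p0 = [None]

    def median_for(gval: float) -> float:
        p = BileParams(
            kappa=params.kappa, R=params.R, T=params.T, c0=params.c0,
            mu=params.mu, p_duct=params.p_duct, g=gval,
        )
        sol = solve_pressure(
            geom, p, tol=solver_tol, rtol=rtol, method=method,
            p0_hint=last_p0[0],
        )
        last_p0[0] = sol.p0
        return zone_pressure_summary(sol, n_zones=n_zones).axis_median

    f0 = median_for(0.0) - target_axis_median
    if abs(f0) <= rel_tol * max(abs(target_axis_median), 1.0):
        return 0.0
    lo, hi = 0.0, 1e-4
    f_hi = median_for(hi) - target_axis_median
    while f_hi < 0:
        lo = hi
        hi *= 4.0
        if hi > g_max:
            raise ValueError(
                f"target axis median {target_axis_median:.6g} Pa is not "
                f"reachable with g <= {g_max:.3g} mol/(m^3 s)"
            )
        f_hi = median_for(hi) - target_axis_median
    g = brentq(
        lambda gv: median_for(gv) - target_axis_median,
        lo, hi, rtol=rel_tol, xtol=1e-12,
    )
    return float(g)


# ---------------------------------------------------------------------------
# conservation diagnostics
# ---------------------------------------------------------------------------

def water_balance_residual(
    sol: PressureSolution,
    geom: RadialGeometry,
    params: BileParams,
    n_fine: int = 4001,
) -> float:
    """Relative residual of L w(L) = int rho kappa A (RT (c - c0) - p) d rho.

    Evaluated from the dense solver output on a fine grid with Simpson
    quadrature; the trivial (no-flow) solution returns 0 exactly.
    """
    from scipy.integrate import simpson

    if sol.dense is None:  # trivial solution: both sides vanish
        return 0.0
    a = sol.rho[0] + sol.start_offset
    r = np.linspace(a, sol.rho[-1], n_fine)
    vals = sol.dense(r)
    u, p = vals[0], vals[1]
    A = np.interp(r, geom.rho, geom.apical_density)
    G = np.interp(r, sol.rho, sol.G)
    c = G / np.maximum(u, 1e-300)
    integrand = r * params.kappa * A * (params.RT * (c - params.c0) - p)
    lhs = u[-1] - u[0]
    rhs = simpson(integrand, x=r)
    scale = max(abs(u[-1]), 1e-300)
    return abs(lhs - rhs) / scale


def osmolyte_balance_residual(
    sol: PressureSolution, geom: RadialGeometry, params: BileParams
) -> float:
    """Max relative residual of rho c w = G beyond the regularization offset."""
    sel = sol.rho > sol.rho[0] + sol.start_offset
    if not np.any(sel):
        return 0.0
    lhs = sol.rho[sel] * sol.c[sel] * sol.w[sel]
    rhs = sol.G[sel]
    scale = np.maximum(np.abs(rhs), np.max(np.abs(rhs)) * 1e-12 + 1e-300)
    return float(np.max(np.abs(lhs - rhs) / scale))
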