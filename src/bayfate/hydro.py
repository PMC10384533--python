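"""Depth-averaged tidal hydrodynamics solved by ADI time stepping.

The model solves the 2-D depth-averaged shallow-water equations

    d(zeta)/dt + d(H_tot U)/dx + d(H_tot V)/dy = 0
    dU/dt + U dU/dx + V dU/dy - f V + g d(zeta)/dx
        + g U sqrt(U^2+V^2) / (H_tot psi^2) = tau_x/(rho0 H_tot) + nu lap(U)
    dV/dt + U dV/dx + V dV/dy + f U + g d(zeta)/dy
        + g V sqrt(U^2+V^2) / (H_tot psi^2) = tau_y/(rho0 H_tot) + nu lap(V)

on an Arakawa-C staggered grid (zeta at cell centers, U and V on faces),
with a Leendertse-style alternating-direction-implicit scheme: each time
step is two half-steps, the first implicit in x (zeta and U solved together
through a tridiagonal system per grid row), the second implicit in y.  Per
full step each velocity receives one implicit (new-level) and one explicit
(old-level) pressure-gradient contribution, a pairing that keeps the
gravity-wave terms neutrally stable at any Courant number, so the
surface-wave CFL condition is not a stability bound; momentum advection,
Coriolis, wind stress and horizontal viscosity are explicit, and the
quadratic Chezy bottom friction is treated semi-implicitly.

Boundary conditions: zero normal flow through closed faces; water level
prescribed by tidal harmonic synthesis on open-boundary cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._tridiag import solve_tridiag_batched
from .forcing import TidalForcing, boundary_elevation
from .grid import BayGrid
from .observations import ObsSeries

logger = logging.getLogger(__name__)

#: Coriolis parameter at 39.4 deg N (2 Omega sin(lat)), 1/s
CORIOLIS_39_4N = float(2.0 * 7.292115e-5 * np.sin(np.deg2rad(39.4)))


class NumericalInstabilityError(RuntimeError):
    """A hydrodynamic or transport field became non-finite or unbounded."""


@dataclass
class HydroParams:
    """Physical and numerical parameters of the tidal model.

    ``chezy`` holds the bottom-roughness value; with ``friction="manning"``
    it is read as a Manning roughness n (s/m^(1/3)) and converted per face
    to a Chezy coefficient psi = H_tot^(1/6)/n, while ``friction="chezy"``
    uses it directly as psi (m^(1/2)/s).  The default roughness 0.035 is a
    typical calibrated coastal value.
    """

    g: float = 9.81              # m/s^2
    rho0: float = 1024.2         # seawater density, kg/m^3
    f: float = CORIOLIS_39_4N    # Coriolis parameter, 1/s
    chezy: float = 0.035         # roughness (meaning set by `friction`)
    friction: str = "manning"    # "manning" | "chezy"
    CD: float = 0.0013           # wind-stress coefficient
    rhoA: float = 1.225          # air density, kg/m^3
    wind_speed: float = 0.0      # W at 10 m, m/s
    wind_dir: float = 0.0        # direction wind blows toward, rad
    eddy_visc: float = 10.1      # horizontal eddy viscosity, m^2/s
    dt: float = 300.0            # time step, s
    min_depth: float = 0.05      # flooding floor for total depth, m
    ramp_s: float = 43200.0      # smooth-start ramp on boundary forcing, s

    def __post_init__(self) -> None:
        if self.g <= 0 or self.rho0 <= 0 or self.chezy <= 0 or self.dt <= 0:
            raise ValueError("g, rho0, chezy and dt must be positive")
        if min(self.CD, self.rhoA, self.eddy_visc, self.wind_speed, self.min_depth) < 0:
            raise ValueError("CD, rhoA, eddy_visc, wind_speed, min_depth must be >= 0")
        if self.friction not in ("manning", "chezy"):
            raise ValueError("friction must be 'manning' or 'chezy'")
        if self.ramp_s < 0:
            raise ValueError("ramp_s must be >= 0")


@dataclass
class HydroState:
    """Free-surface elevation and staggered depth-averaged velocities.

    ``qx``/``qy``, when present, hold the exact face volume fluxes (m^3,
    positive in the +axis direction) that the continuity update moved during
    the step that produced this state; the tracer stage advects with them so
    tracer mass and water volume stay mutually consistent to round-off.
    """

    zeta: np.ndarray          # (nx, ny), m
    U: np.ndarray             # (nx+1, ny), m/s, on x-faces
    V: np.ndarray             # (nx, ny+1), m/s, on y-faces
    t: float = 0.0            # s
    qx: Optional[np.ndarray] = None   # (nx+1, ny), m^3 per step
    qy: Optional[np.ndarray] = None   # (nx, ny+1), m^3 per step

    @classmethod
    def at_rest(cls, grid: BayGrid) -> "HydroState":
        return cls(
            zeta=np.zeros((grid.nx, grid.ny)),
            U=np.zeros((grid.nx + 1, grid.ny)),
            V=np.zeros((grid.nx, grid.ny + 1)),
            t=0.0,
        )

    def center_velocity(self) -> Tuple[np.ndarray, np.ndarray]:
        """Velocity components interpolated to cell centers."""
        uc = 0.5 * (self.U[:-1, :] + self.U[1:, :])
        vc = 0.5 * (self.V[:, :-1] + self.V[:, 1:])
        return uc, vc


def wind_stress(CD: float, rhoA: float, W: float) -> float:
    """Wind-stress magnitude tau = C_D rho_A W^2 (N/m^2); quadratic drag law."""
    if CD < 0 or rhoA < 0 or W < 0:
        raise ValueError("CD, rhoA and W must all be >= 0")
    return CD * rhoA * W * W


def cfl_limit(grid: BayGrid, params: HydroParams, safety_factor: float = 1.0) -> float:
    """Explicit surface-gravity-wave CFL time step (s).

    Returns ``safety_factor * min(dx, dy) / sqrt(g H_max)``.  The ADI scheme
    is implicit in the gravity-wave terms, so exceeding this limit is not an
    instability per se, but :func:`step_hydro` warns when dt exceeds it
    because accuracy of the explicitly treated terms degrades.
    """
    H_max = float(grid.H[grid.wet].max())
    return safety_factor * min(grid.dx, grid.dy) / np.sqrt(params.g * H_max)


def _pad_axis0(u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    um = np.concatenate([u[:1], u[:-1]], axis=0)
    up = np.concatenate([u[1:], u[-1:]], axis=0)
    return um, up


def _pad_axis1(u: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    um = np.concatenate([u[:, :1], u[:, :-1]], axis=1)
    up = np.concatenate([u[:, 1:], u[:, -1:]], axis=1)
    return um, up


def _face_chezy(Hface: np.ndarray, params: HydroParams) -> np.ndarray:
    if params.friction == "chezy":
        return np.full_like(Hface, params.chezy)
    Hsafe = np.maximum(Hface, params.min_depth)
    return Hsafe ** (1.0 / 6.0) / params.chezy


def _half_step(
    zeta: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    H: np.ndarray,
    wet: np.ndarray,
    open_: np.ndarray,
    dx: float,
    dy: float,
    dt: float,
    params: HydroParams,
    zeta_bc: float,
    fsign: float,
    tau_u: float,
    tau_v: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One ADI half-step of dt/2, implicit along axis 0.

    ``u`` lives on axis-0 faces (shape (n0+1, n1)) and is solved together
    with ``zeta``: its axis-0 pressure gradient is fully implicit within the
    sweep, which reduces the coupled system to one tridiagonal problem in
    ``zeta`` per grid line.  ``v`` (axis-1 faces) is advanced explicitly
    with the start-of-sweep level.  Over a full step each velocity then
    receives one explicit (old level) and one implicit (new level) gravity
    contribution; exactly this pairing makes the composed alternating sweep
    neutrally stable in the gravity-wave terms at any Courant number, with
    bottom friction supplying the physical damping.  The y-implicit
    half-step reuses this routine on transposed arrays with the Coriolis
    sign flipped.
    """
    g, nu = params.g, params.eddy_visc
    n0, n1 = zeta.shape
    dth = 0.5 * dt  # each sweep advances half a time step

    Htot = np.where(wet, np.maximum(H + zeta, params.min_depth), 0.0)

    active_u = np.zeros((n0 + 1, n1), dtype=bool)
    active_u[1:-1] = wet[:-1] & wet[1:]
    Hu = np.zeros((n0 + 1, n1))
    Hu[1:-1] = np.where(active_u[1:-1], 0.5 * (Htot[:-1] + Htot[1:]), 0.0)

    active_v = np.zeros((n0, n1 + 1), dtype=bool)
    active_v[:, 1:-1] = wet[:, :-1] & wet[:, 1:]
    Hv = np.zeros((n0, n1 + 1))
    Hv[:, 1:-1] = np.where(active_v[:, 1:-1], 0.5 * (Htot[:, :-1] + Htot[:, 1:]), 0.0)

    # --- explicit terms in the u-momentum equation ------------------------
    vbar = np.zeros_like(u)
    vbar[1:-1] = 0.25 * (v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:])

    u_im1, u_ip1 = _pad_axis0(u)
    u_jm1, u_jp1 = _pad_axis1(u)
    dudx = np.where(u > 0, u - u_im1, u_ip1 - u) / dx
    dudy = np.where(vbar > 0, u - u_jm1, u_jp1 - u) / dy
    lap_u = (u_ip1 - 2 * u + u_im1) / dx**2 + (u_jp1 - 2 * u + u_jm1) / dy**2

    Hu_safe = np.maximum(Hu, params.min_depth)
    psi_u = _face_chezy(Hu, params)
    speed_u = np.hypot(u, vbar)
    r_u = np.where(active_u, g * speed_u / (Hu_safe * psi_u**2), 0.0)

    E_u = (
        -u * dudx
        - vbar * dudy
        + fsign * params.f * vbar
        + tau_u / (params.rho0 * Hu_safe)
        + nu * lap_u
    )

    denom_u = 1.0 + dth * r_u
    G = np.where(active_u, (u + dth * E_u) / denom_u, 0.0)
    beta = np.where(active_u, g * dth / (dx * denom_u), 0.0)

    # --- implicit zeta system (tridiagonal per axis-1 row) ----------------
    div_y = (Hv[:, 1:] * v[:, 1:] - Hv[:, :-1] * v[:, :-1]) / dy

    coef = dth / dx
    a = -coef * Hu[:-1] * beta[:-1]
    c = -coef * Hu[1:] * beta[1:]
    b = 1.0 - a - c
    d = (
        zeta
        - coef * (Hu[1:] * G[1:] - Hu[:-1] * G[:-1])
        - dth * div_y
    )
    # Dirichlet rows: open-boundary cells take the prescribed tide; land
    # cells are inert.  Coupling into them vanishes because Hu = 0 there
    # only on the land side; open cells stay coupled through their faces.
    fixed = open_ | ~wet
    a = np.where(fixed, 0.0, a)
    c = np.where(fixed, 0.0, c)
    b = np.where(fixed, 1.0, b)
    d = np.where(open_, zeta_bc, np.where(~wet, zeta, d))

    zeta_imp = solve_tridiag_batched(a, b, c, d, axis=0)

    u_new = np.zeros_like(u)
    u_new[1:-1] = G[1:-1] - beta[1:-1] * (zeta_imp[1:] - zeta_imp[:-1])
    u_new = np.where(active_u, u_new, 0.0)

    # Recompute zeta in flux form so closed-basin volume telescopes exactly.
    Fx = Hu * u_new
    zeta_new = zeta - dth * ((Fx[1:] - Fx[:-1]) / dx + div_y)
    zeta_new = np.where(open_, zeta_bc, np.where(wet, zeta_new, zeta))

    # --- explicit v update (start-of-sweep level; see stability note) -----
    ubar = np.zeros_like(v)
    ubar[:, 1:-1] = 0.25 * (
        u_new[:-1, :-1] + u_new[1:, :-1] + u_new[:-1, 1:] + u_new[1:, 1:]
    )
    v_im1, v_ip1 = _pad_axis0(v)
    v_jm1, v_jp1 = _pad_axis1(v)
    dvdx = np.where(ubar > 0, v - v_im1, v_ip1 - v) / dx
    dvdy = np.where(v > 0, v - v_jm1, v_jp1 - v) / dy
    lap_v = (v_ip1 - 2 * v + v_im1) / dx**2 + (v_jp1 - 2 * v + v_jm1) / dy**2

    Hv_safe = np.maximum(Hv, params.min_depth)
    psi_v = _face_chezy(Hv, params)
    speed_v = np.hypot(v, ubar)
    r_v = np.where(active_v, g * speed_v / (Hv_safe * psi_v**2), 0.0)

    dzdy = np.zeros_like(v)
    dzdy[:, 1:-1] = (zeta[:, 1:] - zeta[:, :-1]) / dy

    E_v = (
        -ubar * dvdx
        - v * dvdy
        - fsign * params.f * ubar
        + tau_v / (params.rho0 * Hv_safe)
        + nu * lap_v
    )
    v_new = np.where(active_v, (v + dth * (E_v - g * dzdy)) / (1.0 + dth * r_v), 0.0)

    # face fluxes actually used by this sweep's continuity update
    Fv_used = Hv * v
    return zeta_new, u_new, v_new, Fx, Fv_used


def step_hydro(
    state: HydroState,
    grid: BayGrid,
    params: HydroParams,
    forcing: TidalForcing,
) -> HydroState:
    """Advance the flow one time step ``params.dt`` by two ADI half-steps.

    The first half-step is implicit along the channel axis (x), the second
    along the cross-channel axis (y).  Raises
    :class:`NumericalInstabilityError` naming the offending cell and time if
    any field leaves the finite/bounded range.
    """
    dt = params.dt
    limit = cfl_limit(grid, params)
    if dt > limit:
        warnings.warn(
            f"dt={dt:g} s exceeds the explicit gravity-wave CFL limit "
            f"({limit:.2f} s); the ADI scheme remains stable but explicit "
            "terms lose accuracy",
            RuntimeWarning,
            stacklevel=2,
        )
    dt2 = 0.5 * dt
    wet, open_ = grid.wet, grid.open
    tau = wind_stress(params.CD, params.rhoA, params.wind_speed)
    taux = tau * np.cos(params.wind_dir)
    tauy = tau * np.sin(params.wind_dir)

    def _ramp(t: float) -> float:
        # smooth start: avoids shocking the basin with a finite tide at t=0
        if params.ramp_s <= 0 or t >= params.ramp_s:
            return 1.0
        return 0.5 * (1.0 - np.cos(np.pi * t / params.ramp_s))

    bc1 = float(boundary_elevation(forcing, state.t + dt2)) * _ramp(state.t + dt2)
    bc2 = float(boundary_elevation(forcing, state.t + dt)) * _ramp(state.t + dt)

    zeta1, U1, V1, Fx1, Fy1 = _half_step(
        state.zeta, state.U, state.V, grid.H, wet, open_,
        grid.dx, grid.dy, dt, params, bc1, +1.0, taux, tauy,
    )
    zt, vt, ut, Fy2t, Fx2t = _half_step(
        zeta1.T, V1.T, U1.T, grid.H.T, wet.T, open_.T,
        grid.dy, grid.dx, dt, params, bc2, -1.0, tauy, taux,
    )
    zeta2, V2, U2 = zt.T, vt.T, ut.T
    qx = dt2 * grid.dy * (Fx1 + Fx2t.T)
    qy = dt2 * grid.dx * (Fy1 + Fy2t.T)
    t_new = state.t + dt

    bad = ~np.isfinite(zeta2) | (np.abs(zeta2) > 1.0e3)
    if bad.any() or not (np.isfinite(U2).all() and np.isfinite(V2).all()):
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
        else:  # non-finite velocity; report the nearest cell
            arr = np.nan_to_num(np.abs(U2[:-1, :]) + np.abs(V2[:, :-1]), nan=np.inf)
            i, j = map(int, np.unravel_index(np.argmax(arr), arr.shape))
        raise NumericalInstabilityError(
            f"non-finite or unbounded field at cell ({i}, {j}), t={t_new:g} s"
        )
    return HydroState(zeta=zeta2, U=U2, V=V2, t=t_new, qx=qx, qy=qy)


@dataclass
class HydroRun:
    """Result of :func:`run_hydro`: final state plus station records."""

    final: HydroState
    series: Dict[Tuple[Tuple[int, int], str], ObsSeries] = field(default_factory=dict)
    snapshots: List[HydroState] = field(default_factory=list)


def _record_station(state: HydroState, station: Tuple[int, int]) -> Tuple[float, float, float]:
    i, j = station
    uc = 0.5 * (state.U[i, j] + state.U[i + 1, j])
    vc = 0.5 * (state.V[i, j] + state.V[i, j + 1])
    speed = float(np.hypot(uc, vc))
    direction = float(np.degrees(np.arctan2(vc, uc)) % 360.0)
    return float(state.zeta[i, j]), speed, direction


def run_hydro(
    grid: BayGrid,
    params: HydroParams,
    forcing: TidalForcing,
    duration: float,
    stations: Optional[Sequence[Tuple[int, int]]] = None,
    record_stride: int = 1,
    initial: Optional[HydroState] = None,
    snapshot_stride: Optional[int] = None,
) -> HydroRun:
    """Run the tidal model for ``duration`` seconds, recording station series.

    Station records (water level, speed, direction-toward in [0, 360)
    degrees) are taken every ``record_stride`` steps at cell centers.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    stations = list(stations or [])
    n_steps = int(round(duration / params.dt))
    state = initial if initial is not None else HydroState.at_rest(grid)

    times: List[float] = []
    rec: Dict[Tuple[int, int], List[Tuple[float, float, float]]] = {s: [] for s in stations}
    snaps: List[HydroState] = []

    for step in range(1, n_steps + 1):
        state = step_hydro(state, grid, params, forcing)
        if step % record_stride == 0:
            times.append(state.t)
            for s in stations:
                rec[s].append(_record_station(state, s))
        if snapshot_stride and step % snapshot_stride == 0:
            snaps.append(state)

    series: Dict[Tuple[Tuple[int, int], str], ObsSeries] = {}
    t_arr = np.asarray(times)
    for s in stations:
        vals = np.asarray(rec[s])
        for col, quantity in enumerate(("level", "speed", "direction")):
            series[(s, quantity)] = ObsSeries(
                times=t_arr, values=vals[:, col], quantity=quantity, station=s
            )
    return HydroRun(final=state, series=series, snapshots=snaps)
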