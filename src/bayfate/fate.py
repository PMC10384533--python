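"""Multiphase PAH fate: advection-diffusion plus exchange, degradation, settling.

The tracked state variable is the total (16-congener sum) PAH concentration
in the water column, C (ng/L), depth-averaged per cell.  A static phase
partition splits C into organics-bound, biota-bound, freely dissolved and
particulate-adsorbed fractions; only the dissolved fraction exchanges with
the atmosphere and only the particulate fraction settles.

Processes, applied by operator splitting each transport step:

* conservative flux-form first-order upwind advection of the depth-
  integrated tracer, plus explicit turbulent diffusion (sigma_tx, sigma_ty);
* shoreline discharge sources (ng/s per cell);
* air-sea exchange through a two-film volatilization velocity
  k_vol = 1 / (1/k_l + Rg T Ng / (P k_g e^(a1 + a2/T))), sink
  R_vol = k_vol (C - C_equ) / H_tot;
* first-plus-zero-order degradation R = K0 + K1 Kt C;
* Stokes settling of the particulate fraction,
  V0 = omega g d_p^2 (rho_T - rho_0) / (18 nu rho_0), feeding a bed-sediment
  mass balance (C_sed, ng/g dry weight) through a mixed surface layer;
* diffusive/seepage sediment-water exchange with a seepage velocity
  v_p = phi D_sw (C_sed* - C_w) / L_sw, upwinded by the sign of v_p
  (sediment concentration converted to volumetric units via the bulk dry
  density rho_b).

Every kinetic sink is an explicit Euler sub-step clamped so concentrations
never go negative; each clamped increment is charged to an explicit mass
ledger (degraded, volatilized, net-to-bed, sources, boundary) so that a
closed-basin run balances to round-off.

Unit conventions: concentrations ng/L in water, ng/g dry weight in bed
sediment; areal fluxes ng/(m^2 d); kinetic velocities m/d; the time step is
given in seconds and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .grid import BayGrid, SourceSet
from .hydro import HydroState

SECONDS_PER_DAY = 86400.0
L_PER_M3 = 1000.0


@dataclass
class FateParams:
    """Kinetic constants of the multiphase exchange model.

    Defaults follow the calibrated parameter set of the study system where
    one exists; remaining values are representative coastal choices, all
    overridable through configuration.
    """

    sigma_tx: float = 10.1    # turbulent diffusion, m^2/s
    sigma_ty: float = 10.1    # turbulent diffusion, m^2/s
    k_l: float = 4.15         # liquid-film transfer coefficient, m/d
    k_g: float = 0.76         # gas-film transfer coefficient, m/d
    a1: float = 7.2           # volatilization entropy coefficient (dimensionless)
    a2: float = -4000.0       # volatilization enthalpy coefficient, K
    C_equ: float = 0.0        # atmospheric-equilibrium dissolved conc., ng/L
    Tem: float = 15.0         # ambient temperature, deg C
    P: float = 101325.0       # atmospheric pressure, Pa
    Ng: float = 42.3          # moles per m^3 of gas, mol/m^3
    Rg: float = 8.314         # gas constant, J/(mol K)
    phi: float = 0.4          # sediment porosity
    D_sw: float = 0.014       # water-seabed diffusion coefficient, m^2/d
    L_sw: float = 0.1         # overlying-water-layer thickness, m
    K0: float = 0.003         # zero-order degradation, ng/(L d)
    K1: float = 0.017         # first-order degradation, 1/d
    Kt: float = 1.0           # thermodynamic constant
    omega: float = 0.45       # adsorbed-PAH mass fraction on particles
    rhoT: float = 2000.0      # suspended-particle density, kg/m^3
    d_p: float = 5.0e-6       # suspended-particle diameter, m
    Ve: float = 1.5e-6        # seawater kinematic viscosity, m^2/s
    rho0: float = 1024.2      # seawater density, kg/m^3
    g: float = 9.81           # m/s^2
    rho_b: float = 1.3        # bed bulk dry density, kg/L
    sed_mix_depth: float = 0.1  # mixed sediment layer thickness, m

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 1.0 and 0.0 <= self.omega <= 1.0):
            raise ValueError("phi and omega must lie in [0, 1]")
        for name in ("k_l", "k_g", "D_sw", "L_sw", "Ve", "d_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rho_b <= 0 or self.sed_mix_depth <= 0:
            raise ValueError("rho_b and sed_mix_depth must be positive")

    @property
    def rho_b_g_per_L(self) -> float:
        """Bulk dry density in g/L (= ng per (ng/g) per litre of bed)."""
        return self.rho_b * 1000.0

    @property
    def bed_areal_dry_mass(self) -> float:
        """Dry sediment mass per m^2 in the mixed layer (g/m^2)."""
        return self.rho_b * 1.0e6 * self.sed_mix_depth


@dataclass
class PhasePartition:
    """Static phase split of the total concentration (fractions sum to 1)."""

    organics: float = 0.30
    organism: float = 0.15
    dissolved: float = 0.10
    particulate: float = 0.45

    def __post_init__(self) -> None:
        fracs = (self.organics, self.organism, self.dissolved, self.particulate)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("phase fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1.0e-12:
            raise ValueError(f"phase fractions must sum to 1, got {sum(fracs)!r}")


@dataclass
class InitialCondition:
    """Hot-start concentrations: in-bay, outside-boundary, and initial bed."""

    c_inside: float = 0.0    # ng/L
    c_outside: float = 0.0   # ng/L (also the inflow concentration thereafter)
    csed_init: float = 0.0   # ng/g dry weight

    def __post_init__(self) -> None:
        if min(self.c_inside, self.c_outside, self.csed_init) < 0:
            raise ValueError("initial concentrations must be >= 0")


@dataclass
class PAHState:
    """Water, bed and deposition fields of the PAH tracer at one instant."""

    C: np.ndarray          # (nx, ny), ng/L
    C_sed: np.ndarray      # (nx, ny), ng/g dry weight
    dep_rate: np.ndarray   # (nx, ny), ng/(m^2 d), instantaneous settling flux
    dep_cum: np.ndarray    # (nx, ny), ng deposited per cell, cumulative
    t: float = 0.0


@dataclass
class MassLedger:
    """Cumulative mass accounting (ng) over a run; all terms signed as losses
    from the water column except sources/boundary which are gains."""

    degraded: float = 0.0
    volatilized: float = 0.0
    to_bed_net: float = 0.0
    source_in: float = 0.0
    boundary_net: float = 0.0


def hot_start_init(grid: BayGrid, ic: InitialCondition) -> PAHState:
    """Hot-start field: c_inside on interior sea cells, c_outside on the mouth."""
    C = np.zeros((grid.nx, grid.ny))
    C[grid.sea] = ic.c_inside
    C[grid.open] = ic.c_outside
    C_sed = np.where(grid.wet, ic.csed_init, 0.0)
    zeros = np.zeros((grid.nx, grid.ny))
    return PAHState(C=C, C_sed=C_sed, dep_rate=zeros.copy(), dep_cum=zeros.copy(), t=0.0)


def volatilization_coefficient(p: FateParams) -> float:
    """Two-film volatilization velocity k_vol (m/d); bounded by k_l."""
    if p.k_l <= 0 or p.k_g <= 0:
        raise ValueError("film transfer coefficients must be positive")
    TK = p.Tem + 273.15
    gas_resistance = p.Rg * TK * p.Ng / (p.P * p.k_g * np.exp(p.a1 + p.a2 / TK))
    return 1.0 / (1.0 / p.k_l + gas_resistance)


def air_sea_sink(C, p: FateParams, H_total):
    """Net volatilization rate k_vol (C - C_equ)/H_total, ng/(L d).

    Positive values are a loss to the atmosphere; the sign flips to invasion
    when the water is undersaturated (C < C_equ).
    """
    H_total = np.asarray(H_total, dtype=float)
    if np.any(H_total <= 0):
        raise ValueError("H_total must be positive")
    return volatilization_coefficient(p) * (np.asarray(C, float) - p.C_equ) / H_total


def degradation_sink(C, p: FateParams):
    """Combined zero- plus first-order decomposition rate, ng/(L d)."""
    return p.K0 + p.K1 * p.Kt * np.asarray(C, dtype=float)


def settling_velocity(p: FateParams) -> float:
    """Stokes settling velocity of PAH-carrying particles, m/d.

    Physical Stokes law (1/18 factor, kinematic viscosity times water
    density as the dynamic viscosity) scaled by the adsorbed mass fraction
    omega; negative for buoyant particles (rho_T < rho_0).
    """
    v_ms = p.omega * p.g * p.d_p**2 * (p.rhoT - p.rho0) / (18.0 * p.Ve * p.rho0)
    return v_ms * SECONDS_PER_DAY


def sediment_conc_as_water(C_sed, p: FateParams):
    """Convert a bed concentration (ng/g dry) to volumetric units (ng/L)."""
    return np.asarray(C_sed, dtype=float) * p.rho_b_g_per_L


def seepage_velocity(c_sed_star, c_s, p: FateParams):
    """Seepage velocity v_p = phi D_sw (C_sed* - C_s) / L_sw (m/d).

    Both concentrations are volumetric (ng/L); positive v_p is upward
    (sediment to water).  A zero-porosity bed is impermeable.
    """
    if p.L_sw <= 0:
        raise ValueError("L_sw must be positive")
    return p.phi * p.D_sw * (np.asarray(c_sed_star, float) - np.asarray(c_s, float)) / p.L_sw


def bed_exchange_flux(C_w, C_sed, p: FateParams, partition: PhasePartition):
    """Signed sediment-water areal flux, ng/(m^2 d); positive into the water.

    The transported concentration is upwinded by the sign of the seepage
    velocity: the (volumetric) bed concentration when v_p >= 0, the mobile
    water-side fraction (particulate + dissolved) of C_w when v_p < 0.  Both
    branches vanish at v_p = 0, so the flux is continuous there.
    """
    c_star = sediment_conc_as_water(C_sed, p)
    v_p = seepage_velocity(c_star, C_w, p)
    c_up = np.where(
        v_p >= 0,
        c_star,
        np.asarray(C_w, float) * (partition.particulate + partition.dissolved),
    )
    return v_p * c_up * L_PER_M3


def _upwind_face_conc_x(C: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Upwind concentration on interior x-faces; shape (nx-1, ny)."""
    return np.where(U[1:-1] > 0, C[:-1], C[1:])


def _upwind_face_conc_y(C: np.ndarray, V: np.ndarray) -> np.ndarray:
    return np.where(V[:, 1:-1] > 0, C[:, :-1], C[:, 1:])


def step_transport(
    pah: PAHState,
    hydro: HydroState,
    grid: BayGrid,
    p: FateParams,
    partition: PhasePartition,
    sources: SourceSet,
    dt: float,
    c_outside: float = 0.0,
    ledger: Optional[MassLedger] = None,
    enable_kinetics: bool = True,
) -> PAHState:
    """Advance the PAH field one step of ``dt`` seconds.

    Operator split: (i) flux-form upwind advection of the depth-integrated
    tracer with the face depths and velocities of ``hydro``; (ii) explicit
    turbulent diffusion; (iii) source injection; (iv) clamped kinetic
    sub-steps (volatilization, degradation, settling, bed exchange).  Open-
    boundary cells are held at the clean external concentration
    ``c_outside`` (inflow carries it; outflow is advective/zero-gradient).
    """
    wet, open_ = grid.wet, grid.open
    dt_d = dt / SECONDS_PER_DAY
    area = grid.area

    C = pah.C.copy()
    C[open_] = c_outside

    Htot = np.where(wet, np.maximum(grid.H + hydro.zeta, 1.0e-6), 0.0)
    # Face depths mirror the hydrodynamic stepper so advected volume matches.
    active_u = np.zeros((grid.nx + 1, grid.ny), dtype=bool)
    active_u[1:-1] = wet[:-1] & wet[1:]
    Hu = np.zeros((grid.nx + 1, grid.ny))
    Hu[1:-1] = np.where(active_u[1:-1], 0.5 * (Htot[:-1] + Htot[1:]), 0.0)
    active_v = np.zeros((grid.nx, grid.ny + 1), dtype=bool)
    active_v[:, 1:-1] = wet[:, :-1] & wet[:, 1:]
    Hv = np.zeros((grid.nx, grid.ny + 1))
    Hv[:, 1:-1] = np.where(active_v[:, 1:-1], 0.5 * (Htot[:, :-1] + Htot[:, 1:]), 0.0)

    vol_new = Htot * area  # m^3 per cell at the (post-step) hydro level

    # --- advection (flux form, first-order upwind) ------------------------
    if hydro.qx is not None and hydro.qy is not None:
        # Advect with the exact face volume fluxes the hydrodynamic
        # continuity update moved this step; the tracer then sees the same
        # discrete water budget as the free surface, and total tracer mass
        # telescopes to round-off in a closed basin.
        qx, qy = hydro.qx, hydro.qy
        vol_old = vol_new + (qx[1:] - qx[:-1]) + (qy[:, 1:] - qy[:, :-1])
        M = C * vol_old * L_PER_M3
        cu = _upwind_face_conc_x(C, qx)
        cv = _upwind_face_conc_y(C, qy)
        Ax = np.zeros((grid.nx + 1, grid.ny))
        Ax[1:-1] = qx[1:-1] * cu * L_PER_M3  # ng moved per step
        Ay = np.zeros((grid.nx, grid.ny + 1))
        Ay[:, 1:-1] = qy[:, 1:-1] * cv * L_PER_M3
    else:
        # Kinematic fallback for externally supplied flow fields: fluxes
        # from face depths and velocities, volumes frozen at this level.
        vol_old = vol_new
        M = C * vol_old * L_PER_M3
        cu = _upwind_face_conc_x(C, hydro.U)
        cv = _upwind_face_conc_y(C, hydro.V)
        Ax = np.zeros((grid.nx + 1, grid.ny))
        Ax[1:-1] = Hu[1:-1] * hydro.U[1:-1] * cu * grid.dy * L_PER_M3 * dt
        Ay = np.zeros((grid.nx, grid.ny + 1))
        Ay[:, 1:-1] = Hv[:, 1:-1] * hydro.V[:, 1:-1] * cv * grid.dx * L_PER_M3 * dt

    M = M - (Ax[1:] - Ax[:-1] + Ay[:, 1:] - Ay[:, :-1])

    # --- sources ----------------------------------------------------------
    Q = sources.rate_field(grid)
    M += Q * dt

    C = np.where(wet, M / np.maximum(vol_new * L_PER_M3, 1.0e-30), 0.0)

    # --- turbulent diffusion (explicit flux form, substepped for stability)
    if p.sigma_tx > 0 or p.sigma_ty > 0:
        stab = dt * (p.sigma_tx / grid.dx**2 + p.sigma_ty / grid.dy**2)
        n_sub = max(1, int(np.ceil(stab / 0.2)))
        dts = dt / n_sub
        for _ in range(n_sub):
            Dx = np.zeros((grid.nx + 1, grid.ny))
            Dx[1:-1] = (
                -p.sigma_tx * Hu[1:-1] * (C[1:] - C[:-1]) / grid.dx
                * grid.dy * L_PER_M3 * dts
            )
            Dy = np.zeros((grid.nx, grid.ny + 1))
            Dy[:, 1:-1] = (
                -p.sigma_ty * Hv[:, 1:-1] * (C[:, 1:] - C[:, :-1]) / grid.dy
                * grid.dx * L_PER_M3 * dts
            )
            M = C * vol_new * L_PER_M3 - (Dx[1:] - Dx[:-1] + Dy[:, 1:] - Dy[:, :-1])
            C = np.where(wet, M / np.maximum(vol_new * L_PER_M3, 1.0e-30), 0.0)

    C_sed = pah.C_sed.copy()
    dep_rate = np.zeros_like(C)
    dep_cum = pah.dep_cum.copy()

    if ledger is not None:
        ledger.source_in += float(Q.sum() * dt)

    if enable_kinetics:
        water_col = Htot * area * L_PER_M3  # litres per cell
        wet_idx = wet

        # volatilization: clamped Euler relaxation toward C_equ
        k_vol = volatilization_coefficient(p)
        dC = np.where(wet_idx, k_vol * (C - p.C_equ) / np.maximum(Htot, 1e-6) * dt_d, 0.0)
        # do not overshoot the equilibrium concentration in one step
        dC = np.clip(dC, -(np.maximum(p.C_equ - C, 0.0)), np.maximum(C - p.C_equ, 0.0))
        C = C - dC
        if ledger is not None:
            ledger.volatilized += float((dC * water_col).sum())

        # degradation: zero- plus first-order, clamped at zero
        R = degradation_sink(C, p)
        dC = np.where(wet_idx, np.minimum(R * dt_d, C), 0.0)
        dC = np.maximum(dC, 0.0)
        C = C - dC
        if ledger is not None:
            ledger.degraded += float((dC * water_col).sum())

        # Stokes settling of the particulate fraction
        V0 = settling_velocity(p)
        if V0 > 0:
            flux = L_PER_M3 * V0 * partition.particulate * C  # ng/(m^2 d)
            dC = np.where(wet_idx, np.minimum(flux * dt_d / (np.maximum(Htot, 1e-6) * L_PER_M3), C), 0.0)
            flux_eff = dC * np.maximum(Htot, 1e-6) * L_PER_M3 / dt_d
            C = C - dC
            dep_rate = np.where(wet_idx, flux_eff, 0.0)
            dep_cum = dep_cum + np.where(wet_idx, flux_eff * area * dt_d, 0.0)
            C_sed = C_sed + np.where(wet_idx, flux_eff * dt_d / p.bed_areal_dry_mass, 0.0)
            if ledger is not None:
                ledger.to_bed_net += float((dC * water_col).sum())

        # diffusive/seepage bed exchange, upwinded by the sign of v_p
        flux_bed = np.where(wet_idx, bed_exchange_flux(C, C_sed, p, partition), 0.0)
        # clamp: resuspension limited by bed inventory, uptake by water mass
        max_up = C_sed * p.bed_areal_dry_mass / dt_d          # ng/(m^2 d)
        max_down = C * np.maximum(Htot, 1e-6) * L_PER_M3 / dt_d
        flux_bed = np.clip(flux_bed, -max_down, max_up)
        C = C + flux_bed * dt_d / (np.maximum(Htot, 1e-6) * L_PER_M3)
        C_sed = C_sed - flux_bed * dt_d / p.bed_areal_dry_mass
        if ledger is not None:
            ledger.to_bed_net += float((-flux_bed[wet_idx]).sum() * area * dt_d)

    if C.min() < -1.0e-9:
        i, j = map(int, np.argwhere(C == C.min())[0])
        raise RuntimeError(
            f"internal consistency failure: negative concentration {C.min():g} "
            f"at cell ({i}, {j}) after clamping"
        )
    C = np.maximum(C, 0.0)
    C_sed = np.maximum(C_sed, 0.0)

    # open-boundary cells carry the clean external concentration
    if ledger is not None and open_.any():
        before = float((C[open_] * Htot[open_]).sum() * area * L_PER_M3)
        after = float(c_outside * Htot[open_].sum() * area * L_PER_M3)
        # replacing the open-cell water is an exchange with the exterior
        ledger.boundary_net += after - before
    C[open_] = c_outside

    return PAHState(C=C, C_sed=C_sed, dep_rate=dep_rate, dep_cum=dep_cum, t=pah.t + dt)


def total_water_mass(pah: PAHState, hydro: HydroState, grid: BayGrid) -> float:
    """Total tracer mass in the water column (ng): sum C H_tot area."""
    Htot = np.where(grid.wet, np.maximum(grid.H + hydro.zeta, 1.0e-6), 0.0)
    return float((pah.C * Htot).sum() * grid.area * L_PER_M3)


@dataclass
class BedFluxReport:
    """Annualized water-to-sediment flux summary."""

    total_ng_per_year: float
    mean_rate: float   # ng/(m^2 d)
    min_rate: float
    max_rate: float


def annual_bed_flux(dep_rate: np.ndarray, grid: BayGrid) -> BedFluxReport:
    """Annual total deposition: sum over sea cells of rate * area * 365."""
    rates = np.asarray(dep_rate, dtype=float)[grid.wet]
    total = float(rates.sum() * grid.area * 365.0)
    if rates.size == 0:
        return BedFluxReport(0.0, 0.0, 0.0, 0.0)
    return BedFluxReport(
        total_ng_per_year=total,
        mean_rate=float(rates.mean()),
        min_rate=float(rates.min()),
        max_rate=float(rates.max()),
    )
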