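# Methods

`bayfate` simulates the fate, transport and human-health risk of polycyclic
aromatic hydrocarbons (ΣPAHs, the 16 USEPA priority congeners tracked as a
single total) in an idealized semi-closed narrow bay, and provides the
validation and calibration machinery such a model needs.  This note records
the model equations as implemented, the numerical choices, the synthetic
study conditions, and the known limitations.

## Hydrodynamics

Depth-averaged shallow-water equations on a rectilinear Arakawa-C grid
(`zeta` at cell centers, `U`, `V` on faces):

    ∂ζ/∂t + ∂(H_tot U)/∂x + ∂(H_tot V)/∂y = 0
    ∂U/∂t + U∂U/∂x + V∂U/∂y − fV + g∂ζ/∂x + g U√(U²+V²)/(H_tot ψ²)
        = τx/(ρ₀H_tot) + ν∇²U        (V-equation analogous, +fU)

with `H_tot = H + ζ` floored at `min_depth` (no wetting/drying; the modelled
depths are 5–25 m).  The open boundary (one full short side, the mouth)
carries a prescribed water level from harmonic synthesis over astronomical
constituents (M2, S2, N2, K2, K1, O1, P1, Q1, M1 supported); the other three
sides are closed (zero normal flow).

**Time stepping.**  Alternating-direction-implicit (Leendertse-type): each
step is two half-steps of dt/2; the first solves ζ and U implicitly along x
(one tridiagonal system in ζ per grid row after eliminating U), the second
solves ζ and V implicitly along y.  Within a sweep the implicit-direction
pressure gradient is treated fully implicitly while the cross velocity is
updated explicitly with the start-of-sweep level.  Over a full step each
velocity therefore receives one implicit (new-level) and one explicit
(old-level) gravity contribution; a von Neumann analysis of the composed
scheme shows this pairing is neutrally stable for the gravity-wave terms at
any Courant number (any partially implicit within-sweep weighting is not),
with bottom friction supplying the physical damping.  Advection (first-order
upwind), Coriolis, wind stress and horizontal viscosity are explicit;
quadratic bottom friction is semi-implicit.  ζ is finally recomputed in flux
form, so closed-basin volume telescopes to round-off.

**Bottom friction.**  The roughness parameter supports two readings: a
Chézy coefficient ψ used directly, or (default) a Manning roughness n
converted per face as ψ = H_tot^(1/6)/n.  The default n = 0.035 s/m^(1/3)
is a standard calibrated coastal value; the calibration machinery scans n
over [0.02, 0.06].

**Smooth start.**  The boundary tide is ramped over `ramp_s` (default 12 h)
with a half-cosine; starting a basin at rest against a finite tidal
elevation otherwise launches a shock that the explicit advection terms
cannot survive at the operational time step.

**Time step.**  The default dt = 300 s deliberately exceeds the explicit
surface-gravity-wave CFL limit (~16 s on the study grid) — that limit does
not bind the ADI scheme.  `step_hydro` emits a warning (not a clamp) when
dt exceeds `cfl_limit`, since the accuracy of the explicitly treated terms
degrades with dt.  Verified behaviour: lake-at-rest is preserved exactly;
closed-basin volume is conserved to round-off over thousands of steps; the
frictionless co-oscillation in a uniform channel reproduces the analytic
amplification 1/cos(kL) to better than 0.1% at dt up to 300 s.

## PAH fate and transport

The water-column state is the total concentration C (ng/L), split by a
static phase partition (organics 30%, biota 15%, freely dissolved 10%,
particulate 45% by default — constants, not sorption kinetics).  One
transport step applies, by operator splitting:

1. **Advection** — conservative flux-form first-order upwind of the
   depth-integrated tracer.  The fluxes are the *exact* face volume fluxes
   exported by the hydrodynamic continuity update (`HydroState.qx/qy`), so
   the tracer sees the same discrete water budget as the free surface and
   closed-basin tracer mass is conserved to round-off.  Positivity is
   preserved by upwinding.
2. **Turbulent diffusion** — explicit flux form with σ_tx, σ_ty
   (default 10.1 m²/s), internally sub-stepped to respect the explicit
   diffusion stability bound.
3. **Sources** — point discharges in ng/s per cell.
4. **Kinetics**, each an explicit Euler sub-step clamped so no
   concentration crosses zero, with every increment charged to a mass
   ledger (degraded / volatilized / net-to-bed / source / boundary); for a
   closed basin the ledger closes the budget to round-off:
   - *Air–sea exchange*: two-film velocity
     k_vol = 1/(1/k_l + R_g T N_g /(P k_g e^(a1+a2/T))), sink
     k_vol (C − C_equ)/H_tot applied to the bulk concentration.  With
     N_g = P/(R_g T) the gas-side term reduces to 1/(k_g H_c) with
     H_c = e^(a1+a2/T) a dimensionless Henry constant; the defaults
     a1 = 7.2, a2 = −4000 K give H_c ≈ 1.3×10⁻³ at 15 °C
     (phenanthrene-like), i.e. gas-film-limited volatilization, which is
     the realistic regime for PAHs.
   - *Degradation*: R = K₀ + K₁K_t C (defaults 0.003 ng/(L·d),
     0.017 d⁻¹, 1).
   - *Stokes settling* of the particulate fraction:
     V₀ = ω g d_p² (ρ_T − ρ₀)/(18 ν ρ₀), i.e. the physically correct
     Stokes law scaled by the adsorbed mass fraction ω; the settling flux
     feeds a bed mass balance through a mixed sediment layer
     (`sed_mix_depth`, 0.1 m) with bulk dry density ρ_b (1.3 kg/L).
   - *Sediment–water exchange*: seepage velocity
     v_p = φ D_sw (C_sed* − C_s)/L_sw with the bed concentration converted
     to volumetric units via ρ_b (C_sed* = C_sed·ρ_b) and C_s identified
     with the overlying-water concentration.  The transported concentration
     is upwinded by the sign of v_p (bed side when v_p ≥ 0, the mobile
     particulate+dissolved water fraction when v_p < 0), making the flux
     continuous at v_p = 0.

   A consequence of the ρ_b conversion worth stating plainly: the bed
   equilibrates where C_sed* ≈ C_w, i.e. at a tiny C_sed ≈ C_w/ρ_b, and it
   reaches that state within hours at the default exchange rate.  Past
   that point the bed *mirrors* settling (seepage returns what deposition
   delivers), so the long-run net water→sediment flux is governed by the
   exchange terms rather than by raw settling.  The sedimentation-rate
   field and annual bed flux reported by the analysis are the gross
   settling flux, which is what a sediment-trap observation measures.

Open-boundary cells are held at the clean external concentration
(inflow carries it; outflow is advective).  The hot start initializes the
in-bay field at a monitored-range concentration rather than zero.

## Validation and calibration

**Willmott skill.**  Skill = 1 − Σ|M−D|²/Σ(|M−D̄|+|D−D̄|)², rated poor
(≤0.2), medium (≤0.5), good (≤0.7), excellent (>0.7); boundary values take
the lower band.  Flow directions are compared on the circle (wrapped
angular difference) before scoring.  The denominator vanishes only in the
fully degenerate M = D = const case, which scores 1 by convention.

**Dynamic equilibrium.**  A station series is declared equilibrated at the
earliest window boundary from which k consecutive window-mean changes are
each below a relative tolerance.  Defaults for the study analysis: 1-day
windows (≈ two semidiurnal cycles, so tidal oscillation averages out),
tol = 2%, k = 3.  The rule detects stabilization of the local mean; it
cannot distinguish a very slow secular drift whose per-window increments
stay below tolerance — an inherent property of any windowed-change rule.

**Calibration.**  Cyclic coordinate descent: each of the five transport
parameters (Ve [10⁻⁶ m²/s], Ψ [Manning n], k_g, k_l [m/d], D_sw [m²/d]) is
scanned over its declared number of evenly spaced trials within bounds
(defaults 7/48/9/12/3 over their default ranges, 79 evaluations per pass),
the others held at the incumbent vector; the incumbent always moves to the
scan best (ties toward the lower value) so the search can walk along
correlated parameter valleys, and the reported optimum is the best-scoring
vector in the trace.  Objectives: Willmott skill (maximized; default) or
RMS misfit (minimized).  Failed forward runs are logged, recorded as null
in the trace and skipped.

**Identifiability and the recovery testbed.**  The five parameters act on
a single station concentration series largely through quasi-uniform
gain/decay factors, so they are strongly collinear under the study-default
kinetics; in particular k_l is *structurally unidentifiable* there (its
whole bound range moves k_vol by parts per million when volatilization is
gas-film limited), and the bed mirror (above) strips the viscosity Ve of
its settling lever.  The parameter-recovery exercise therefore runs on a
designed testbed (`study.make_calibration_forward`): a 30×10-cell reduced
bay, 2-day forward runs at dt = 600 s, with fixed (non-calibrated)
constants chosen for identifiability — a volatile-compound regime
(H_c ≈ 10) so the liquid film carries weight, a low-permeability bed
(φ = 0.05, L_sw = 1 m) so settling stays a net sink over the horizon, and
coarse particles (d_p = 15 μm).  Recovery uses the RMS objective: with
noise-free observations the discriminating skill differences of weakly
sensitive parameters fall below double precision near skill = 1, while
absolute RMS differences remain resolvable.  On this testbed a three-pass
scan recovers all five parameters exactly (objective 0) from noise-free
synthetic observations generated at grid-aligned truths.

## Risk assessment

Sediment ΣPAHs are converted to a benzo[a]pyrene toxic-equivalent
concentration TEQ = ΣC_i·TEF_i using the published 16-congener TEF table;
when only the simulated total is available, a representative (synthetic)
coastal congener mixture supplies the per-total TEQ factor (≈0.081 TEQ per
unit ΣPAHs).  Incremental lifetime cancer risks follow the standard USEPA
forms for ingestion and dermal contact with BaP slope factors 7.3 and
3.85 (mg/(kg·d))⁻¹ and the usual adult exposure defaults; their sum is
banded negligible (<10⁻⁶), potential ([10⁻⁶, 10⁻⁴]) or high (>10⁻⁴), the
boundary values belonging to the potential band.  The inhalation pathway
(PEF) is carried in configuration but unused — no implemented equation
requires it.

## The synthetic study conditions

All real inputs of the motivating system (coastline, bathymetry, tide-gauge
harmonics, monitoring series) are unavailable; the package ships one fully
synthetic study scenario as its default configuration:

- 60×20-cell rectilinear channel, 15 km × 4 km, depth shoaling linearly
  from 15 m at the open mouth to 5 m at the closed head;
- mixed macrotidal forcing M2/S2/K1/O1 = 1.2/0.45/0.3/0.2 m, phases 0;
- three shoreline outfalls (two along the flank, one adjacent to the
  head), each 120 μg/s of ΣPAHs (1.2×10⁸ ng/s);
- hot start at 50 ng/L in-bay over clean (0 ng/L) external water and a
  clean initial bed;
- monitoring stations at the mouth (i=2) and near the head (i=56),
  mid-channel; dt = 300 s, 60 simulated days, deposition averaged after a
  5-day spin-up.

These values were fixed once, on realism grounds (a narrow macrotidal bay
with shoreline discharges, pollutant levels in the tens-to-hundreds of
ng/L).  Under them the bay reproduces the qualitative regime of interest:
tidal currents weaken monotonically from mouth to head; the mouth station
reaches dynamic equilibrium in ~12 days while the head takes ~25; the
time-mean settling flux grows toward the head; and the maximum ΣILCR falls
in the head third, at the 10⁻⁶–10⁻⁵ (potential-risk) level.

What the generator does *not* emulate: curvilinear coastline geometry,
wind-driven and baroclinic circulation, seasonal temperature/discharge
cycles, congener-resolved partitioning, and observation error structure
beyond independent Gaussian noise.  Passing tests therefore demonstrate
internal correctness and the right qualitative physics, not agreement with
any real bay's numbers.

## Problem sizes used by the test and acceptance runs

Chosen to keep a complete run cheap while leaving every assertion
meaningful: the coupled study runs the full 60 days on the 60×20 grid; the
channel fidelity checks use a 100-cell channel (kL = 1); transport
fidelity a 600-cell 1-D domain; conservation checks 24×8 closed basins
over 1000 steps; calibration exercises the 30×10 reduced bay with 2-day
forwards (79 evaluations per pass, 3 passes for recovery).

## Known limitations

- First-order upwind advection is diffusive; the Gaussian-patch check
  quantifies the numerical diffusivity (u·dx/2·(1−Courant)) and the test
  resolution keeps it at ~1% of the physical diffusivity.
- The bed module is a single mixed layer with the ρ_b volumetric
  conversion mandated by the exchange formulation; as noted, it saturates
  quickly and then mirrors settling.  No diagenesis, burial below the
  mixed layer, or sorption kinetics.
- The mass ledger is exact for closed basins; at a tidally varying open
  boundary the Dirichlet level creates/destroys water volume at the
  boundary cells, so the boundary term is approximate there.
- Calibration is a deterministic scan — no uncertainty quantification.
- Equilibration detection is windowed-change based and inherits that
  rule's blindness to sufficiently slow drifts.
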