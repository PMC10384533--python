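import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayfate.coupled import run_coupled
from bayfate.fate import (
    FateParams,
    InitialCondition,
    MassLedger,
    PAHState,
    PhasePartition,
    step_transport,
    total_water_mass,
)
from bayfate.forcing import make_default_forcing
from bayfate.grid import SourceSet
from bayfate.hydro import HydroParams, HydroState, step_hydro

from .conftest import closed_basin


def make_pah(grid, C):
    zeros = np.zeros((grid.nx, grid.ny))
    return PAHState(C=np.asarray(C, float), C_sed=zeros.copy(),
                    dep_rate=zeros.copy(), dep_cum=zeros.copy(), t=0.0)


class TestPureTransport:
    def test_no_flow_no_kinetics_is_identity(self, basin):
        hydro = HydroState.at_rest(basin)
        pah = make_pah(basin, np.random.default_rng(0).uniform(1, 5, (basin.nx, basin.ny)))
        fp = FateParams(sigma_tx=0.0, sigma_ty=0.0)
        out = step_transport(pah, hydro, basin, fp, PhasePartition(), SourceSet(), 300.0,
                             enable_kinetics=False)
        # identity up to the mass-form round trip (one ulp)
        np.testing.assert_allclose(out.C, pah.C, rtol=1e-14)

    def test_closed_basin_tracer_mass_conserved_under_flow(self, basin):
        zeta0 = np.zeros((basin.nx, basin.ny))
        zeta0[:6, :] = 0.3
        hydro = HydroState(zeta=zeta0, U=np.zeros((basin.nx + 1, basin.ny)),
                           V=np.zeros((basin.nx, basin.ny + 1)))
        hp = HydroParams(dt=30.0, friction="chezy", chezy=60.0, eddy_visc=1.0)
        fp = FateParams(sigma_tx=5.0, sigma_ty=5.0)
        C0 = np.ones((basin.nx, basin.ny))
        C0[10:14, 3:6] = 5.0
        pah = make_pah(basin, C0)
        forcing = make_default_forcing({})
        m0 = total_water_mass(pah, hydro, basin)
        for _ in range(1000):
            hydro = step_hydro(hydro, basin, hp, forcing)
            pah = step_transport(pah, hydro, basin, fp, PhasePartition(), SourceSet(),
                                 hp.dt, enable_kinetics=False)
        m1 = total_water_mass(pah, hydro, basin)
        assert abs(m1 - m0) / m0 <= 1e-8
        assert pah.C.min() >= 0

    def test_gaussian_patch_advects_and_spreads_like_closed_form(self):
        # uniform 1-D flow; compare centroid speed and variance growth
        nx, dx = 600, 10.0
        grid = closed_basin(nx=nx, ny=1, dx=dx, dy=dx, depth=5.0)
        u0, dt, sigma = 0.5, 19.0, 12.5
        U = np.full((nx + 1, 1), u0)
        U[0] = U[-1] = 0.0
        hydro = HydroState(zeta=np.zeros((nx, 1)), U=U, V=np.zeros((nx, 2)))
        fp = FateParams(sigma_tx=sigma, sigma_ty=0.0)
        x = (np.arange(nx) + 0.5) * dx
        x0, s0 = 1500.0, 100.0
        pah = make_pah(grid, np.exp(-0.5 * ((x - x0) / s0) ** 2)[:, None])
        n_steps = 125
        for _ in range(n_steps):
            pah = step_transport(pah, hydro, grid, fp, PhasePartition(), SourceSet(),
                                 dt, enable_kinetics=False)
        t_tot = n_steps * dt
        w = pah.C[:, 0]
        centroid = float((x * w).sum() / w.sum())
        variance = float(((x - centroid) ** 2 * w).sum() / w.sum())
        assert centroid - x0 == pytest.approx(u0 * t_tot, rel=0.02)
        assert variance - s0**2 == pytest.approx(2 * sigma * t_tot, rel=0.02)

    def test_transport_commutes_with_grid_mirroring(self, basin):
        rng = np.random.default_rng(5)
        zeta0 = rng.uniform(-0.1, 0.1, (basin.nx, basin.ny))
        zeta0 = 0.5 * (zeta0 + zeta0[:, ::-1])  # symmetric free surface
        hydro = HydroState(zeta=zeta0, U=np.zeros((basin.nx + 1, basin.ny)),
                           V=np.zeros((basin.nx, basin.ny + 1)))
        hp = HydroParams(dt=30.0, f=0.0, friction="chezy", chezy=60.0)
        fp = FateParams(sigma_tx=5.0, sigma_ty=5.0)
        C0 = rng.uniform(1, 5, (basin.nx, basin.ny))
        C0 = 0.5 * (C0 + C0[:, ::-1])
        pah = make_pah(basin, C0)
        forcing = make_default_forcing({})
        for _ in range(50):
            hydro = step_hydro(hydro, basin, hp, forcing)
            pah = step_transport(pah, hydro, basin, fp, PhasePartition(), SourceSet(),
                                 hp.dt, enable_kinetics=False)
        np.testing.assert_allclose(pah.C, pah.C[:, ::-1], atol=1e-12)


class TestMassLedger:
    def test_closed_basin_ledger_balances(self, basin):
        """initial - final + sources = degraded + volatilized + net-to-bed."""
        zeta0 = np.zeros((basin.nx, basin.ny))
        zeta0[:8, :] = 0.2
        hydro = HydroState(zeta=zeta0, U=np.zeros((basin.nx + 1, basin.ny)),
                           V=np.zeros((basin.nx, basin.ny + 1)))
        hp = HydroParams(dt=60.0, friction="chezy", chezy=60.0)
        fp = FateParams()
        sources = SourceSet(entries=[((12, 4), 1.0e6)])
        pah = make_pah(basin, np.full((basin.nx, basin.ny), 50.0))
        pah.C_sed[:] = 0.05
        ledger = MassLedger()
        forcing = make_default_forcing({})
        m0 = total_water_mass(pah, hydro, basin)
        for _ in range(300):
            hydro = step_hydro(hydro, basin, hp, forcing)
            pah = step_transport(pah, hydro, basin, fp, PhasePartition(), sources,
                                 hp.dt, ledger=ledger, enable_kinetics=True)
        m1 = total_water_mass(pah, hydro, basin)
        balance = m0 + ledger.source_in - ledger.degraded - ledger.volatilized \
            - ledger.to_bed_net
        assert m1 == pytest.approx(balance, rel=1e-6)

    def test_deposition_accumulates_in_cumulative_field(self, basin):
        hydro = HydroState.at_rest(basin)
        pah = make_pah(basin, np.full((basin.nx, basin.ny), 100.0))
        fp = FateParams(sigma_tx=0.0, sigma_ty=0.0)
        out = step_transport(pah, hydro, basin, fp, PhasePartition(), SourceSet(), 3600.0)
        assert out.dep_cum.sum() > 0
        assert np.all(out.dep_rate >= 0)


class TestNonNegativity:
    @settings(max_examples=25)
    @given(
        K1=st.floats(0.0, 5.0),
        k_l=st.floats(0.1, 50.0),
        omega=st.floats(0.0, 1.0),
        d_p=st.floats(1e-6, 1e-4),
        Dsw=st.floats(0.012, 0.15),
        phi=st.floats(0.0, 1.0),
        csed=st.floats(0.0, 50.0),
        dt=st.floats(60.0, 3600.0),
    )
    def test_concentrations_stay_non_negative(self, K1, k_l, omega, d_p, Dsw, phi, csed, dt):
        grid = closed_basin(nx=8, ny=4)
        hydro = HydroState.at_rest(grid)
        fp = FateParams(K1=K1, k_l=k_l, omega=omega, d_p=d_p, D_sw=Dsw, phi=phi,
                        sigma_tx=1.0, sigma_ty=1.0)
        pah = make_pah(grid, np.full((8, 4), 10.0))
        pah.C_sed[:] = csed
        for _ in range(5):
            pah = step_transport(pah, hydro, grid, fp, PhasePartition(), SourceSet(), dt)
        assert pah.C.min() >= 0.0
        assert pah.C_sed.min() >= 0.0


class TestDepositionMonotonicity:
    def test_larger_particles_never_decrease_annual_flux(self, basin):
        from bayfate.fate import annual_bed_flux

        totals = []
        for d_p in (2e-6, 5e-6, 2e-5):
            hydro = HydroState.at_rest(basin)
            fp = FateParams(d_p=d_p, sigma_tx=0.0, sigma_ty=0.0)
            pah = make_pah(basin, np.full((basin.nx, basin.ny), 100.0))
            out = step_transport(pah, hydro, basin, fp, PhasePartition(), SourceSet(), 600.0)
            totals.append(annual_bed_flux(out.dep_rate, basin).total_ng_per_year)
        assert totals[0] <= totals[1] <= totals[2]


class TestRunCoupled:
    def test_zero_everything_stays_zero(self):
        from bayfate.grid import build_idealized_bay

        grid = build_idealized_bay(12, 5, 3000.0, 1000.0, 5.0, 15.0)
        res = run_coupled(
            grid=grid,
            hydro_params=HydroParams(dt=300.0),
            forcing=make_default_forcing({"M2": 0.8}),
            fate_params=FateParams(C_equ=0.0, K0=0.0),
            partition=PhasePartition(),
            ic=InitialCondition(0.0, 0.0, 0.0),
            sources=SourceSet(),
            duration=43200.0,
            stations=[(6, 2)],
        )
        assert np.all(res.pah_final.C == 0.0)
        assert np.all(res.pah_final.C_sed == 0.0)
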