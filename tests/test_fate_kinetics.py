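import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bayfate.fate import (
    FateParams,
    InitialCondition,
    PhasePartition,
    air_sea_sink,
    annual_bed_flux,
    bed_exchange_flux,
    degradation_sink,
    hot_start_init,
    sediment_conc_as_water,
    seepage_velocity,
    settling_velocity,
    volatilization_coefficient,
)
from bayfate.grid import build_idealized_bay

from .conftest import closed_basin


def params(**kw):
    return FateParams(**kw)


class TestVolatilizationCoefficient:
    def test_liquid_film_limit_when_gas_film_fast(self):
        p = params(k_g=1.0e12, a1=0.0, a2=0.0)
        assert volatilization_coefficient(p) == pytest.approx(p.k_l, rel=1e-9)

    def test_monotone_increasing_in_k_l(self):
        lo = volatilization_coefficient(params(k_l=2.0))
        hi = volatilization_coefficient(params(k_l=4.0))
        assert hi > lo

    def test_equal_resistance_halves_k_l(self):
        # Ng = P/(Rg T) makes Rg T Ng / P = 1 exactly; k_g = k_l and a
        # unit Henry factor then put equal resistance in both films.
        Tem = 15.0
        Ng = 101325.0 / (8.314 * (Tem + 273.15))
        p = params(k_l=4.15, k_g=4.15, a1=0.0, a2=0.0, Tem=Tem, Ng=Ng)
        assert volatilization_coefficient(p) == pytest.approx(4.15 / 2, rel=1e-12)

    def test_bounded_by_k_l(self):
        p = params()
        assert 0 < volatilization_coefficient(p) <= p.k_l


class TestAirSeaSink:
    def test_equilibrium_gives_zero(self):
        p = params(C_equ=5.0)
        assert air_sea_sink(5.0, p, 10.0) == pytest.approx(0.0, abs=1e-15)

    def test_reference_value(self):
        # k_vol forced to exactly 1 m/d via the liquid-film limit
        p = params(k_l=1.0, k_g=1e15, a1=0.0, a2=0.0, C_equ=0.0)
        assert air_sea_sink(10.0, p, 10.0) == pytest.approx(1.0, rel=1e-9)

    def test_sign_flips_for_undersaturation(self):
        p = params(C_equ=20.0)
        assert air_sea_sink(10.0, p, 10.0) < 0

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            air_sea_sink(10.0, params(), 0.0)

    @given(
        C=st.floats(0, 1e4),
        C_equ=st.floats(0, 100),
        H=st.floats(0.1, 50),
        k_l=st.floats(4.12, 4.19),
        k_g=st.floats(0.73, 0.78),
    )
    def test_matches_independent_formula(self, C, C_equ, H, k_l, k_g):
        p = params(k_l=k_l, k_g=k_g, C_equ=C_equ)
        TK = p.Tem + 273.15
        k_vol = 1.0 / (
            1.0 / k_l
            + p.Rg * TK * p.Ng / (p.P * k_g * np.exp(p.a1 + p.a2 / TK))
        )
        expected = k_vol * (C - C_equ) / H
        assert air_sea_sink(C, p, H) == pytest.approx(expected, rel=1e-12, abs=1e-300)


class TestDegradationSink:
    def test_zero_at_origin_without_constant_term(self):
        assert degradation_sink(0.0, params(K0=0.0)) == 0.0

    def test_printed_constants_reference_value(self):
        # K0 = 0.003 ng/(L d), K1 = 0.017 1/d, Kt = 1, C = 100 ng/L
        assert degradation_sink(100.0, params()) == pytest.approx(1.703, rel=1e-12)

    @given(C=st.floats(0, 1e6), K1=st.floats(0, 1), Kt=st.floats(0.1, 10))
    def test_affine_with_slope_K1_Kt(self, C, K1, Kt):
        p = params(K1=K1, Kt=Kt)
        base = degradation_sink(0.0, p)
        assert degradation_sink(C, p) == pytest.approx(base + K1 * Kt * C, rel=1e-12, abs=1e-12)


class TestSettlingVelocity:
    def test_neutral_buoyancy_gives_zero(self):
        assert settling_velocity(params(rhoT=1024.2)) == pytest.approx(0.0, abs=1e-15)

    def test_zero_adsorbed_fraction_gives_zero(self):
        assert settling_velocity(params(omega=0.0)) == 0.0

    def test_stokes_law_reference_value(self):
        # independent hand arithmetic: omega g d^2 (rhoT-rho0)/(18 nu rho0)
        p = params(omega=1.0, d_p=50e-6, rhoT=2000.0, rho0=1024.2, Ve=1.5e-6)
        expected_ms = 1.0 * 9.81 * (50e-6) ** 2 * (2000.0 - 1024.2) / (
            18.0 * 1.5e-6 * 1024.2
        )
        assert settling_velocity(p) == pytest.approx(expected_ms * 86400.0, rel=1e-12)

    def test_buoyant_particles_rise(self):
        assert settling_velocity(params(rhoT=900.0)) < 0

    @given(
        omega=st.floats(0, 1),
        d_p=st.floats(1e-6, 1e-4),
        rhoT=st.floats(1100, 2700),
        Ve=st.floats(1.44e-6, 1.57e-6),
    )
    def test_matches_independent_formula(self, omega, d_p, rhoT, Ve):
        p = params(omega=omega, d_p=d_p, rhoT=rhoT, Ve=Ve)
        expected = omega * p.g * d_p**2 * (rhoT - p.rho0) / (18 * Ve * p.rho0) * 86400.0
        assert settling_velocity(p) == pytest.approx(expected, rel=1e-12, abs=1e-300)


class TestSeepageAndBedExchange:
    def test_no_gradient_no_seepage(self):
        assert seepage_velocity(100.0, 100.0, params()) == 0.0

    def test_impermeable_bed(self):
        assert seepage_velocity(500.0, 0.0, params(phi=0.0)) == 0.0

    def test_reference_value(self):
        p = params(phi=0.5, D_sw=0.014, L_sw=0.1)
        assert seepage_velocity(100.0, 0.0, p) == pytest.approx(7.0, rel=1e-12)

    def test_flux_zero_at_zero_seepage(self):
        p = params()
        c_sed = 130.0 / p.rho_b_g_per_L  # C_sed* == C_w == 130 ng/L
        assert bed_exchange_flux(130.0, c_sed, p, PhasePartition()) == pytest.approx(0.0, abs=1e-9)

    def test_upward_flux_carries_bed_concentration(self):
        p = params()
        part = PhasePartition()
        c_sed = 200.0 / p.rho_b_g_per_L * 2  # C_sed* = 400 > C_w = 0
        c_star = sediment_conc_as_water(c_sed, p)
        v_p = seepage_velocity(c_star, 0.0, p)
        assert v_p > 0
        assert bed_exchange_flux(0.0, c_sed, p, part) == pytest.approx(
            v_p * c_star * 1000.0, rel=1e-12
        )

    def test_downward_flux_carries_mobile_water_fraction(self):
        p = params()
        part = PhasePartition()
        flux = bed_exchange_flux(100.0, 0.0, p, part)
        v_p = seepage_velocity(0.0, 100.0, p)
        assert v_p < 0 and flux < 0
        assert flux == pytest.approx(
            v_p * 100.0 * (part.particulate + part.dissolved) * 1000.0, rel=1e-12
        )

    def test_continuity_at_vanishing_seepage(self):
        p = params()
        part = PhasePartition()
        c_w = 130.0
        c_sed_eq = c_w / p.rho_b_g_per_L
        for eps in (1e-8, -1e-8):
            flux = bed_exchange_flux(c_w, c_sed_eq * (1 + eps), p, part)
            assert abs(flux) < 1.0


class TestHotStart:
    def test_zero_everywhere_for_zero_ic(self):
        grid = build_idealized_bay(6, 4, 600.0, 400.0, 5.0, 10.0)
        state = hot_start_init(grid, InitialCondition(0.0, 0.0, 0.0))
        assert np.all(state.C == 0.0)

    def test_interior_and_boundary_values(self):
        grid = build_idealized_bay(6, 4, 600.0, 400.0, 5.0, 10.0)
        state = hot_start_init(grid, InitialCondition(50.0, 10.0, 2.0))
        assert np.all(state.C[grid.sea] == 50.0)
        assert np.all(state.C[grid.open] == 10.0)
        assert np.all(state.C_sed[grid.wet] == 2.0)
        assert np.all(state.dep_cum == 0.0)

    def test_initial_mass_consistent_with_volume_weighted_sum(self):
        grid = build_idealized_bay(6, 4, 600.0, 400.0, 10.0, 10.0)
        ic = InitialCondition(50.0, 50.0, 0.0)
        state = hot_start_init(grid, ic)
        mass = float((state.C * grid.H).sum() * grid.area * 1000.0)
        volume_L = float(grid.H[grid.wet].sum() * grid.area * 1000.0)
        assert mass == pytest.approx(ic.c_inside * volume_L, rel=1e-12)

    def test_negative_ic_rejected(self):
        with pytest.raises(ValueError):
            InitialCondition(-1.0, 0.0, 0.0)


class TestAnnualBedFlux:
    def test_uniform_rate_reference_value(self):
        grid = closed_basin(nx=10, ny=10, dx=1000.0, dy=1000.0)  # 1e8 m^2 total
        report = annual_bed_flux(np.full((10, 10), 10.0), grid)
        assert report.total_ng_per_year == pytest.approx(3.65e11, rel=1e-12)
        assert report.mean_rate == pytest.approx(10.0)

    def test_zero_field(self):
        grid = closed_basin(nx=4, ny=4)
        assert annual_bed_flux(np.zeros((4, 4)), grid).total_ng_per_year == 0.0

    def test_linearity(self):
        grid = closed_basin(nx=5, ny=4)
        rng = np.random.default_rng(3)
        field = rng.uniform(0, 20, size=(5, 4))
        one = annual_bed_flux(field, grid).total_ng_per_year
        two = annual_bed_flux(2 * field, grid).total_ng_per_year
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(phi=1.5), dict(omega=-0.1), dict(k_l=0.0), dict(d_p=-1e-6), dict(L_sw=0.0)],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            FateParams(**kw)

    def test_partition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PhasePartition(organics=0.3, organism=0.15, dissolved=0.1, particulate=0.4)
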