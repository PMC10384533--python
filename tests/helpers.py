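"""Shared numerical checks used by both the unit and acceptance suites."""

import numpy as np

from bayfate.forcing import angular_frequency, make_default_forcing
from bayfate.grid import OPEN, SEA, BayGrid
from bayfate.hydro import HydroParams, HydroState, step_hydro


def tidal_channel(nx=100, depth=10.0, kL=1.0):
    """A 1-cell-wide uniform channel whose length gives the requested kL
    for the M2 constituent."""
    omega = angular_frequency("M2")
    k = omega / np.sqrt(9.81 * depth)
    dx = (kL / k) / nx
    mask = np.full((nx, 1), SEA, dtype=np.int8)
    mask[0, 0] = OPEN
    grid = BayGrid(nx, 1, dx, dx, np.full((nx, 1), depth), mask)
    return grid, omega, k


def standing_wave_head_amplitude(
    chezy=1.0e6,
    amp=0.01,
    dt=120.0,
    nx=100,
    depth=10.0,
    kL=1.0,
    spin_periods=10,
    fit_periods=8,
):
    """Measured and predicted co-oscillation amplitude at the channel head.

    Runs the tidal channel to a periodic state (boundary amplitude ramped
    over the spin-up to avoid exciting undamped free seiche modes) and fits
    the M2 harmonic at the head cell.  The linear frictionless prediction
    is amp * cos(k dx/2) / cos(k (nx - 1/2) dx): the closed wall is an
    antinode and the mouth cell center carries the prescribed amplitude.
    """
    grid, omega, k = tidal_channel(nx=nx, depth=depth, kL=kL)
    period = 2 * np.pi / omega
    params = HydroParams(
        dt=dt, friction="chezy", chezy=chezy, eddy_visc=0.0, f=0.0,
        ramp_s=0.8 * spin_periods * period,
    )
    forcing = make_default_forcing({"M2": amp})
    state = HydroState.at_rest(grid)
    while state.t < spin_periods * period:
        state = step_hydro(state, grid, params, forcing)
    times, heads = [], []
    t_end = state.t + fit_periods * period
    while state.t < t_end:
        state = step_hydro(state, grid, params, forcing)
        times.append(state.t)
        heads.append(state.zeta[-1, 0])
    times = np.asarray(times)
    design = np.c_[np.cos(omega * times), np.sin(omega * times)]
    coef, *_ = np.linalg.lstsq(design, np.asarray(heads), rcond=None)
    measured = float(np.hypot(*coef))
    predicted = amp * np.cos(k * grid.dx / 2) / np.cos(k * (nx - 0.5) * grid.dx)
    return measured, predicted


def run_closed_basin_volume_drift(grid, n_steps=1000, dt=20.0):
    """Relative total-volume drift of a closed basin started from a bump."""
    zeta0 = np.zeros((grid.nx, grid.ny))
    zeta0[grid.nx // 4 : grid.nx // 4 + 3, grid.ny // 3 : grid.ny // 3 + 2] = 0.5
    state = HydroState(
        zeta=zeta0.copy(),
        U=np.zeros((grid.nx + 1, grid.ny)),
        V=np.zeros((grid.nx, grid.ny + 1)),
    )
    params = HydroParams(dt=dt, friction="chezy", chezy=50.0, eddy_visc=1.0)
    forcing = make_default_forcing({})
    vol0 = float(((grid.H + state.zeta) * grid.area).sum())
    for _ in range(n_steps):
        state = step_hydro(state, grid, params, forcing)
    vol1 = float(((grid.H + state.zeta) * grid.area).sum())
    return abs(vol1 - vol0) / vol0, state


def lake_at_rest_deviation(grid, n_steps=100, dt=60.0):
    """Max |zeta|, |U|, |V| after stepping an unforced basin at rest."""
    params = HydroParams(dt=dt)
    forcing = make_default_forcing({})
    state = HydroState.at_rest(grid)
    for _ in range(n_steps):
        state = step_hydro(state, grid, params, forcing)
    return (
        float(np.abs(state.zeta).max()),
        float(np.abs(state.U).max()),
        float(np.abs(state.V).max()),
    )
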