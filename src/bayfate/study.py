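"""The standard synthetic-bay study: one end-to-end scenario, analyzed.

This module wires the whole pipeline together on the idealized bay the
package ships as its study condition: a 60 x 20-cell, 15 km x 4 km channel
shoaling from 15 m at the mouth to 5 m at the head, forced by a mixed
M2+S2+K1+O1 tide, with three shoreline outfalls (one adjacent to the head).
It exposes the scenario pieces, a coupled-run driver, and the summary
metrics of the analysis chain: along-channel hydrodynamic gradient,
equilibration times, sedimentation accounting, and the ILCR risk map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats

from .config import RunConfig, load_config
from .coupled import CoupledResult, run_coupled
from .fate import annual_bed_flux, BedFluxReport
from .grid import BayGrid
from .risk import ILCRParams, RiskResult, mixture_teq_factor, risk_map
from .validation import equilibration_time, willmott_skill
from .observations import synthesize_observations

SECONDS_PER_DAY = 86400.0


@dataclass
class StudyResult:
    config: RunConfig
    grid: BayGrid
    coupled: CoupledResult
    stations: Dict[str, Tuple[int, int]]


def run_study(
    cfg: Optional[RunConfig] = None,
    duration_days: Optional[float] = None,
) -> StudyResult:
    """Run the standard coupled scenario (defaults: 60 simulated days)."""
    cfg = cfg or load_config(None)
    grid = cfg.build_grid()
    stations = cfg.stations()
    days = duration_days if duration_days is not None else cfg.run["duration_days"]
    result = run_coupled(
        grid=grid,
        hydro_params=cfg.build_hydro_params(),
        forcing=cfg.build_forcing(),
        fate_params=cfg.build_fate_params(),
        partition=cfg.build_partition(),
        ic=cfg.build_ic(),
        sources=cfg.build_sources(),
        duration=days * SECONDS_PER_DAY,
        stations=list(stations.values()),
        record_stride=cfg.run["record_stride"],
        dep_spinup=cfg.run["dep_spinup_days"] * SECONDS_PER_DAY,
    )
    return StudyResult(config=cfg, grid=grid, coupled=result, stations=stations)


def thirds_slices(nx: int) -> Tuple[slice, slice, slice]:
    """Along-channel thirds: mouth, middle, head."""
    a, b = nx // 3, 2 * nx // 3
    return slice(0, a), slice(a, b), slice(b, nx)


def speed_third_means(mean_speed: np.ndarray, grid: BayGrid) -> np.ndarray:
    """Mean of a cell-center speed field over the along-channel thirds."""
    thirds = thirds_slices(grid.nx)
    out = []
    for sl in thirds:
        block = mean_speed[sl]
        wet = grid.wet[sl]
        out.append(float(block[wet].mean()))
    return np.asarray(out)


def speed_gradient_spearman(third_means: np.ndarray) -> float:
    """Spearman rho of third-mean speed against distance from the mouth."""
    rho, _ = stats.spearmanr(np.arange(len(third_means)), third_means)
    return float(rho)


def station_equilibration_days(
    study: StudyResult,
    window_days: float = 1.0,
    tol: float = 0.02,
    k: int = 3,
) -> Dict[str, Optional[float]]:
    """Equilibration time (days) of the concentration series per station."""
    from .validation import InsufficientDataError

    out: Dict[str, Optional[float]] = {}
    for name, cell in study.stations.items():
        series = study.coupled.series[(cell, "concentration")]
        try:
            t = equilibration_time(series, window_days * SECONDS_PER_DAY, tol, k)
        except InsufficientDataError:
            t = None
        out[name] = None if t is None else t / SECONDS_PER_DAY
    return out


def deposition_third_means(study: StudyResult) -> np.ndarray:
    """Time-mean deposition rate (ng/(m^2 d)) over the along-channel thirds."""
    dep = study.coupled.mean_dep_rate
    thirds = thirds_slices(study.grid.nx)
    out = []
    for sl in thirds:
        block = dep[sl]
        wet = study.grid.wet[sl]
        out.append(float(block[wet].mean()))
    return np.asarray(out)


def sediment_risk(study: StudyResult, params: Optional[ILCRParams] = None) -> RiskResult:
    """Risk map over the end-of-run sediment field via the mixture TEQ factor."""
    params = params or study.config.build_risk_params()
    teq = study.coupled.pah_final.C_sed * mixture_teq_factor()
    return risk_map(teq, params, mask=study.grid.sea)


def max_risk_third(study: StudyResult, risk: Optional[RiskResult] = None) -> int:
    """Index (0=mouth, 2=head) of the along-channel third holding the max ILCR."""
    risk = risk or sediment_risk(study)
    total = np.where(study.grid.sea, risk.ilcr_total, -np.inf)
    i, _ = np.unravel_index(np.argmax(total), total.shape)
    thirds = thirds_slices(study.grid.nx)
    for t_idx, sl in enumerate(thirds):
        if sl.start <= i < sl.stop:
            return t_idx
    raise AssertionError("unreachable")


_QUANTITY_SEED_OFFSET = {"level": 1, "speed": 2, "direction": 3, "concentration": 4}


def station_skill(study: StudyResult, noise_sd: float, seed: int) -> Dict[str, float]:
    """Willmott skill of the model against noisy pseudo-observations.

    Emulates the validation exercise: the model series plus station noise
    plays the role of the independent observations.  Noise standard
    deviations scale with the natural size of each quantity.
    """
    out: Dict[str, float] = {}
    for q_idx, (name, cell) in enumerate(study.stations.items()):
        for quantity, sd in (
            ("level", noise_sd * 0.1),
            ("speed", noise_sd * 0.05),
            ("concentration", noise_sd),
        ):
            truth = study.coupled.series[(cell, quantity)]
            sub_seed = seed + 31 * q_idx + _QUANTITY_SEED_OFFSET[quantity]
            obs = synthesize_observations(truth, sd, sub_seed)
            rep = willmott_skill(truth.values, obs.values)
            out[f"{name}_{quantity}"] = rep.skill
    return out


def study_summary(study: StudyResult, seed: int = 0) -> Dict[str, float]:
    """Scalar metrics of the full analysis chain for one study run."""
    thirds = speed_third_means(study.coupled.mean_speed, study.grid)
    eq = station_equilibration_days(study)
    dep_thirds = deposition_third_means(study)
    flux: BedFluxReport = annual_bed_flux(study.coupled.mean_dep_rate, study.grid)
    risk = sediment_risk(study)
    summary = {
        "speed_third_mouth_m_s": thirds[0],
        "speed_third_mid_m_s": thirds[1],
        "speed_third_head_m_s": thirds[2],
        "speed_gradient_spearman": speed_gradient_spearman(thirds),
        "equilibration_mouth_days": eq.get("mouth"),
        "equilibration_head_days": eq.get("head"),
        "dep_rate_mouth_third": dep_thirds[0],
        "dep_rate_head_third": dep_thirds[2],
        "dep_rate_mean": flux.mean_rate,
        "annual_bed_flux_ng": flux.total_ng_per_year,
        "ilcr_total_min": risk.min_total,
        "ilcr_total_max": risk.max_total,
        "max_risk_third": float(max_risk_third(study, risk)),
    }
    return summary


def make_calibration_forward(
    nx: int = 30,
    ny: int = 10,
    forward_days: float = 2.0,
    dt: float = 600.0,
    station: Tuple[int, int] = (20, 5),
):
    """Forward-run closure for calibration exercises on a reduced bay.

    Maps a calibration vector (keys Ve [1e-6 m^2/s], Psi [Manning n],
    kg/kl [m/d], Dsw [m^2/d]; missing keys keep defaults) to the station
    concentration series of a short coupled run.  The reduced grid and
    horizon keep a full coordinate-descent scan affordable while every
    parameter still leaves a deterministic imprint on the series.

    The fixed (non-calibrated) testbed constants are chosen for parameter
    identifiability rather than to mimic the default study compound: a
    volatile-compound regime (dimensionless Henry constant ~10 at 15 degC)
    so the liquid film carries a measurable share of the two-film
    resistance -- under the gas-film-limited default realistic for heavy
    PAHs, k_l is structurally unidentifiable from a concentration series --
    a low-permeability bed (small porosity, thick overlying layer) so
    settling remains a net sink over the horizon and the viscosity Ve
    keeps its lever, and coarse suspended particles for the same reason.
    """
    import dataclasses

    from .coupled import run_coupled
    from .fate import FateParams, InitialCondition, PhasePartition
    from .forcing import make_default_forcing
    from .grid import SourceSet, build_idealized_bay
    from .hydro import HydroParams

    grid = build_idealized_bay(nx, ny, 8000.0, 2000.0, 5.0, 12.0)
    forcing = make_default_forcing({"M2": 1.2, "S2": 0.45, "K1": 0.3, "O1": 0.2})
    partition = PhasePartition()
    ic = InitialCondition(c_inside=50.0, c_outside=0.0, csed_init=0.0)
    sources = SourceSet(entries=[((nx - 3, 2), 1.2e8)])

    def forward(params: Dict[str, float]):
        hp = HydroParams(dt=dt, chezy=params.get("Psi", 0.035))
        fp_updates = {"a1": 16.184, "phi": 0.05, "L_sw": 1.0, "d_p": 1.5e-5}
        if "Ve" in params:
            fp_updates["Ve"] = params["Ve"] * 1.0e-6
        if "Dsw" in params:
            fp_updates["D_sw"] = params["Dsw"]
        if "kg" in params:
            fp_updates["k_g"] = params["kg"]
        if "kl" in params:
            fp_updates["k_l"] = params["kl"]
        fp = dataclasses.replace(FateParams(), **fp_updates)
        res = run_coupled(
            grid=grid,
            hydro_params=hp,
            forcing=forcing,
            fate_params=fp,
            partition=partition,
            ic=ic,
            sources=sources,
            duration=forward_days * SECONDS_PER_DAY,
            stations=[station],
            record_stride=3,
        )
        return res.series[(station, "concentration")]

    return forward
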