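"""Run configuration: defaults, YAML loading, validation, round-tripping.

A run configuration is a nested mapping with one section per pipeline
stage.  Loading merges the file over the built-in defaults, rejects unknown
keys (naming the offending key), and eagerly constructs every typed object
so invariant violations surface at load time with the failing constraint.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import yaml

from .calibration import CalibrationSpec, ParamSpec
from .fate import FateParams, InitialCondition, PhasePartition
from .forcing import TidalForcing, make_default_forcing
from .grid import BayGrid, SourceSet, build_idealized_bay
from .hydro import CORIOLIS_39_4N, HydroParams
from .risk import ILCRParams

logger = logging.getLogger(__name__)

DEFAULTS: Dict[str, Any] = {
    "grid": {
        "nx": 60,
        "ny": 20,
        "length_m": 15000.0,
        "width_m": 4000.0,
        "depth_mouth_m": 15.0,
        "depth_head_m": 5.0,
    },
    "forcing": {
        # mixed semidiurnal/diurnal macrotidal forcing typical of a
        # mid-latitude semi-closed bay
        "amplitudes": {"M2": 1.2, "S2": 0.45, "K1": 0.3, "O1": 0.2},
        "phases": {},
    },
    "hydro": {
        "g": 9.81,
        "rho0": 1024.2,
        "f": CORIOLIS_39_4N,  # 39.4 deg N
        "chezy": 0.035,
        "friction": "manning",
        "CD": 0.0013,
        "rhoA": 1.225,
        "wind_speed": 0.0,
        "wind_dir": 0.0,
        "eddy_visc": 10.1,
        "dt": 300.0,
        "min_depth": 0.05,
        "ramp_s": 43200.0,
    },
    "fate": {
        "sigma_tx": 10.1,
        "sigma_ty": 10.1,
        "k_l": 4.15,
        "k_g": 0.76,
        "a1": 7.2,
        "a2": -4000.0,
        "C_equ": 0.0,
        "Tem": 15.0,
        "P": 101325.0,
        "Ng": 42.3,
        "Rg": 8.314,
        "phi": 0.4,
        "D_sw": 0.014,
        "L_sw": 0.1,
        "K0": 0.003,
        "K1": 0.017,
        "Kt": 1.0,
        "omega": 0.45,
        "rhoT": 2000.0,
        "d_p": 5.0e-6,
        "Ve": 1.5e-6,
        "rho0": 1024.2,
        "g": 9.81,
        "rho_b": 1.3,
        "sed_mix_depth": 0.1,
    },
    "partition": {
        "organics": 0.30,
        "organism": 0.15,
        "dissolved": 0.10,
        "particulate": 0.45,
    },
    # shoreline outfalls along the bay, one adjacent to the head;
    # 120 ug/s = 1.2e8 ng/s of total PAHs per designated source cell
    "sources": [
        {"i": 14, "j": 2, "q_ng_per_s": 1.2e8},
        {"i": 35, "j": 2, "q_ng_per_s": 1.2e8},
        {"i": 56, "j": 3, "q_ng_per_s": 1.2e8},
    ],
    # hot start: monitored-range in-bay concentration; clean exterior
    "ic": {"c_inside": 50.0, "c_outside": 0.0, "csed_init": 0.0},
    "stations": [
        {"name": "mouth", "i": 2, "j": 10},
        {"name": "head", "i": 56, "j": 10},
    ],
    "run": {
        "duration_days": 60.0,
        "record_stride": 6,
        "seed": 0,
        "dep_spinup_days": 5.0,
    },
    "calibration": {
        "objective": "max_skill",
        "passes": 1,
        # Ve in 1e-6 m^2/s; Psi is the Manning roughness; Dsw in m^2/d;
        # kg, kl in m/d.  Trial counts follow the calibrated-run budget.
        "params": [
            {"name": "Ve", "lower": 1.44, "upper": 1.57, "trials": 7},
            {"name": "Psi", "lower": 0.02, "upper": 0.06, "trials": 48},
            {"name": "kg", "lower": 0.73, "upper": 0.78, "trials": 9},
            {"name": "kl", "lower": 4.12, "upper": 4.19, "trials": 12},
            {"name": "Dsw", "lower": 0.012, "upper": 0.015, "trials": 3},
        ],
    },
    "risk": {
        "EF": 350.0,
        "ED": 40.0,
        "IR": 100.0,
        "SA": 5700.0,
        "AF": 0.07,
        "ABS": 0.13,
        "AT": 25550.0,
        "BW": 70.0,
        "CSF_ing": 7.3,
        "CSF_derm": 3.85,
        "PEF": 1.36e9,
    },
}

def _merge(defaults: Any, override: Any, path: str) -> Any:
    if override is None:
        return copy.deepcopy(defaults)
    if isinstance(defaults, dict):
        if not isinstance(override, dict):
            raise ValueError(f"config key {path!r} must be a mapping")
        out = copy.deepcopy(defaults)
        for key, value in override.items():
            child = f"{path}.{key}" if path else str(key)
            if key not in defaults:
                # forcing amplitude/phase maps accept any supported name
                if path in ("forcing.amplitudes", "forcing.phases"):
                    out[key] = value
                    continue
                raise ValueError(f"unknown config key {child!r}")
            out[key] = _merge(defaults[key], value, child)
        return out
    return copy.deepcopy(override)


@dataclass
class RunConfig:
    """A fully merged, validated run configuration."""

    data: Dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __post_init__(self) -> None:
        self.validate()

    # --- typed builders ---------------------------------------------------
    def build_grid(self) -> BayGrid:
        g = self.data["grid"]
        return build_idealized_bay(
            nx=g["nx"], ny=g["ny"], length_m=g["length_m"], width_m=g["width_m"],
            depth_head_m=g["depth_head_m"], depth_mouth_m=g["depth_mouth_m"],
        )

    def build_forcing(self) -> TidalForcing:
        fc = self.data["forcing"]
        return make_default_forcing(fc["amplitudes"], fc["phases"])

    def build_hydro_params(self) -> HydroParams:
        return HydroParams(**self.data["hydro"])

    def build_fate_params(self) -> FateParams:
        return FateParams(**self.data["fate"])

    def build_partition(self) -> PhasePartition:
        return PhasePartition(**self.data["partition"])

    def build_sources(self) -> SourceSet:
        return SourceSet(
            entries=[((s["i"], s["j"]), s["q_ng_per_s"]) for s in self.data["sources"]]
        )

    def build_ic(self) -> InitialCondition:
        return InitialCondition(**self.data["ic"])

    def build_calibration_spec(self) -> CalibrationSpec:
        c = self.data["calibration"]
        return CalibrationSpec(
            params=[ParamSpec(**p) for p in c["params"]],
            objective=c["objective"],
            passes=c["passes"],
        )

    def build_risk_params(self) -> ILCRParams:
        return ILCRParams(**self.data["risk"])

    def stations(self) -> Dict[str, Tuple[int, int]]:
        return {s["name"]: (s["i"], s["j"]) for s in self.data["stations"]}

    @property
    def run(self) -> Dict[str, Any]:
        return self.data["run"]

    def validate(self) -> None:
        """Construct every typed object so invariants fail loudly at load."""
        grid = self.build_grid()
        self.build_forcing()
        self.build_hydro_params()
        self.build_fate_params()
        self.build_partition()
        self.build_sources().validate(grid)
        self.build_ic()
        self.build_calibration_spec()
        self.build_risk_params()
        for s in self.data["stations"]:
            i, j = s["i"], s["j"]
            if not (0 <= i < grid.nx and 0 <= j < grid.ny) or not grid.wet[i, j]:
                raise ValueError(f"station {s['name']!r} at ({i}, {j}) is not a wet cell")


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a YAML config, merged over defaults; ``None``/empty file = defaults.

    Unknown keys and invariant violations raise ``ValueError`` naming the
    key or constraint.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping at top level")
    merged = _merge(DEFAULTS, raw, "")
    cfg = RunConfig(data=merged)
    logger.info("effective configuration loaded from %s", path)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective (defaults-merged) configuration as YAML."""
    Path(path).write_text(yaml.safe_dump(cfg.data, sort_keys=True))
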