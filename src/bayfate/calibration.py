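"""Bounded coordinate-descent calibration against station observations.

The five tunable transport parameters (seawater viscosity Ve, bed roughness
Psi, gas- and liquid-film coefficients kg/kl, and the water-seabed
diffusion coefficient Dsw) are calibrated by scanning each parameter over
evenly spaced trial values within its bounds while holding the others at
the incumbent vector -- a deterministic realization of manual one-at-a-time
tuning.  The per-parameter trial counts are part of the specification of a
calibration run, so a single pass evaluates exactly the sum of the counts.

The objective is either the Willmott skill of the forward-run series
against the observations (maximized; the default) or the RMS misfit
(minimized).  Ties break toward the lower parameter value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .observations import ObsSeries
from .validation import willmott_skill

logger = logging.getLogger(__name__)

CALIBRATABLE = ("Ve", "Dsw", "Psi", "kg", "kl")


class CalibrationError(RuntimeError):
    """Every forward run of a calibration scan failed."""


@dataclass
class ParamSpec:
    """One calibratable parameter: bounds and number of scan trials."""

    name: str
    lower: float
    upper: float
    trials: int

    def __post_init__(self) -> None:
        if self.name not in CALIBRATABLE:
            raise ValueError(
                f"unknown calibration parameter {self.name!r}; "
                f"supported: {', '.join(CALIBRATABLE)}"
            )
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.trials < 2:
            raise ValueError(f"{self.name}: trial count must be >= 2")

    def grid(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.trials)

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / (self.trials - 1)


@dataclass
class CalibrationSpec:
    """Scan layout, objective and pass count for one calibration run."""

    params: Sequence[ParamSpec]
    objective: str = "max_skill"
    passes: int = 1

    def __post_init__(self) -> None:
        if self.objective not in ("max_skill", "min_rmse"):
            raise ValueError("objective must be 'max_skill' or 'min_rmse'")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in calibration spec")

    @property
    def evaluations_per_pass(self) -> int:
        return sum(p.trials for p in self.params)


@dataclass
class CalibrationResult:
    best: Dict[str, float]
    objective_value: float
    trace: List[Tuple[Dict[str, float], Optional[float]]] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        rows = []
        for idx, (params, obj) in enumerate(self.trace):
            row = {"trial": idx, **params, "objective": obj}
            rows.append(row)
        return pd.DataFrame(rows)

    def write_trace_csv(self, path: Union[str, Path]) -> None:
        self.trace_frame().to_csv(path, index=False)


def _score(
    model: Union[np.ndarray, ObsSeries],
    obs: ObsSeries,
    objective: str,
) -> float:
    """Higher-is-better internal score for either objective."""
    values = model.values if isinstance(model, ObsSeries) else np.asarray(model, float)
    if values.shape != obs.values.shape:
        raise ValueError("forward run returned a series of mismatched length")
    if objective == "max_skill":
        return willmott_skill(values, obs.values).skill
    rmse = float(np.sqrt(np.mean((values - obs.values) ** 2)))
    return -rmse


def calibrate(
    spec: CalibrationSpec,
    obs: ObsSeries,
    forward: Callable[[Dict[str, float]], Union[np.ndarray, ObsSeries]],
) -> CalibrationResult:
    """Coordinate-descent scan of the calibration parameters.

    ``forward`` maps a parameter dict (keys as in ``spec.params``) to a
    model series aligned sample-for-sample with ``obs``; it must be
    deterministic for a fixed vector.  Parameters are scanned in their
    declared order, each over ``trials`` evenly spaced values within its
    bounds with the others held at the incumbent vector; a scan's best value
    (ties toward the lower value) replaces the incumbent when it improves
    the best score seen.  Failed forward runs are recorded in the trace with
    a null objective and skipped; a scan in which every trial fails raises
    :class:`CalibrationError`.

    The returned best vector is the best-scoring vector in the trace, so the
    reported objective always equals the trace optimum.
    """
    incumbent: Dict[str, float] = {
        p.name: 0.5 * (p.lower + p.upper) for p in spec.params
    }
    trace: List[Tuple[Dict[str, float], Optional[float]]] = []
    best_vec: Optional[Dict[str, float]] = None
    best_score = -np.inf

    for _ in range(spec.passes):
        for pspec in spec.params:
            scan_best_val: Optional[float] = None
            scan_best_score = -np.inf
            any_ok = False
            for value in pspec.grid():
                trial = dict(incumbent)
                trial[pspec.name] = float(value)
                try:
                    model = forward(trial)
                    score = _score(model, obs, spec.objective)
                except Exception as exc:  # pragma: no cover - exercised in tests
                    warnings.warn(
                        f"forward run failed at {pspec.name}={value:g}: {exc}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    trace.append((trial, None))
                    continue
                any_ok = True
                trace.append((trial, score))
                if score > scan_best_score:  # strict: ties keep the lower value
                    scan_best_score = score
                    scan_best_val = float(value)
            if not any_ok:
                raise CalibrationError(
                    f"all {pspec.trials} forward runs failed while scanning "
                    f"{pspec.name}"
                )
            # always move to the scan best: cyclic descent must be able to
            # walk along correlated parameter valleys
            incumbent[pspec.name] = scan_best_val
            if scan_best_score >= best_score:
                best_score = scan_best_score
                best_vec = dict(incumbent)

    assert best_vec is not None
    objective_value = best_score if spec.objective == "max_skill" else -best_score
    return CalibrationResult(best=best_vec, objective_value=objective_value, trace=trace)
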