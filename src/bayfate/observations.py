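"""Station time series and synthetic noisy pseudo-observations.

Observed quantities are tagged by name: ``"level"`` (m), ``"speed"`` (m/s),
``"direction"`` (degrees, toward), ``"concentration"`` (ng/L).  Pseudo-
observations emulate quality-control station records by adding independent
zero-mean Gaussian noise to a model truth series; the noise model is
deliberately the simplest one sufficient to exercise calibration and skill
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Tuple

import numpy as np
import pandas as pd

QUANTITIES = ("level", "speed", "direction", "concentration")


@dataclass
class ObsSeries:
    """A station time series: strictly increasing times, finite values."""

    times: np.ndarray  # seconds since simulation start
    values: np.ndarray
    quantity: str
    station: Tuple[int, int]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("series must be non-empty")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.times)


def synthesize_observations(truth: ObsSeries, noise_sd: float, seed: int) -> ObsSeries:
    """Add independent N(0, noise_sd^2) noise to a truth series.

    The same ``(truth, noise_sd, seed)`` triple reproduces the output
    bit-for-bit.  ``noise_sd = 0`` returns the truth values unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, 1.0, size=len(truth)) * noise_sd
    return replace(truth, values=truth.values + noise)


def write_obs_csv(series: List[ObsSeries] | ObsSeries, path: str | Path) -> None:
    """Write observation series as CSV: time_s, quantity, station_i, station_j, value."""
    if isinstance(series, ObsSeries):
        series = [series]
    frames = [
        pd.DataFrame(
            {
                "time_s": s.times,
                "quantity": s.quantity,
                "station_i": s.station[0],
                "station_j": s.station[1],
                "value": s.values,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_obs_csv(path: str | Path) -> List[ObsSeries]:
    """Read the ObsSeries CSV dialect back into a list of series."""
    df = pd.read_csv(path)
    required = {"time_s", "quantity", "station_i", "station_j", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    out: List[ObsSeries] = []
    for (quantity, si, sj), g in df.groupby(
        ["quantity", "station_i", "station_j"], sort=True
    ):
        g = g.sort_values("time_s")
        out.append(
            ObsSeries(
                times=g["time_s"].to_numpy(),
                values=g["value"].to_numpy(),
                quantity=str(quantity),
                station=(int(si), int(sj)),
            )
        )
    return out
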