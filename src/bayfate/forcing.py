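"""Tidal constituents and harmonic open-boundary forcing.

The open boundary is driven by a harmonic synthesis over astronomical tidal
constituents: zeta_b(t) = sum_k a_k cos(omega_k t - phi_k).  Angular
frequencies are fixed by astronomy (stored as the standard constituent
speeds in degrees per mean solar hour); amplitudes and phases are free
inputs, as they would come from a harmonic analysis of local tide-gauge
records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np

# Standard constituent speeds, degrees per mean solar hour.
_SPEED_DEG_PER_HOUR: Dict[str, float] = {
    "M2": 28.9841042,
    "S2": 30.0,
    "N2": 28.4397295,
    "K2": 30.0821373,
    "K1": 15.0410686,
    "O1": 13.9430356,
    "P1": 14.9589314,
    "Q1": 13.3986609,
    "M1": 14.4966939,
}

SUPPORTED_CONSTITUENTS = tuple(sorted(_SPEED_DEG_PER_HOUR))


def angular_frequency(name: str) -> float:
    """Canonical angular frequency (rad/s) of a named constituent."""
    try:
        speed = _SPEED_DEG_PER_HOUR[name]
    except KeyError:
        raise ValueError(
            f"unknown tidal constituent {name!r}; supported: "
            + ", ".join(SUPPORTED_CONSTITUENTS)
        ) from None
    return speed * np.pi / (180.0 * 3600.0)


@dataclass(frozen=True)
class Constituent:
    name: str
    omega: float  # rad/s
    amplitude: float  # m
    phase: float  # rad

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"constituent {self.name}: angular frequency must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"constituent {self.name}: amplitude must be >= 0")


@dataclass
class TidalForcing:
    """A set of tidal constituents with unique names."""

    constituents: List[Constituent] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.constituents]
        if len(set(names)) != len(names):
            raise ValueError("constituent names must be unique")

    def elevation(self, t) -> np.ndarray | float:
        """Harmonic synthesis at time(s) ``t`` (seconds); 0 for empty forcing."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c in self.constituents:
            out = out + c.amplitude * np.cos(c.omega * t - c.phase)
        return out if out.ndim else float(out)


def make_default_forcing(
    amplitudes: Mapping[str, float],
    phases: Optional[Mapping[str, float]] = None,
) -> TidalForcing:
    """Build a :class:`TidalForcing` from amplitude (m) and phase (rad) maps.

    Every key of ``amplitudes`` must be a supported constituent name; its
    canonical angular frequency is filled in automatically.  Missing phases
    default to zero.  Empty maps give a still tide.
    """
    phases = dict(phases or {})
    for name in phases:
        if name not in _SPEED_DEG_PER_HOUR:
            raise ValueError(
                f"unknown tidal constituent {name!r}; supported: "
                + ", ".join(SUPPORTED_CONSTITUENTS)
            )
    constituents = [
        Constituent(
            name=name,
            omega=angular_frequency(name),
            amplitude=float(amp),
            phase=float(phases.get(name, 0.0)),
        )
        for name, amp in amplitudes.items()
    ]
    return TidalForcing(constituents=constituents)


def boundary_elevation(forcing: TidalForcing, t) -> np.ndarray | float:
    """Open-boundary water level (m) at time(s) ``t`` seconds since start."""
    return forcing.elevation(t)
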