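"""Benzo[a]pyrene toxic equivalents and incremental lifetime cancer risk.

Sediment PAH burdens are expressed as a BaP toxic-equivalent concentration

    TEQ = sum_i C_i TEF_i        (ng/g dry weight)

over the 16 USEPA priority congeners, and converted into incremental
lifetime cancer risks for the ingestion and dermal-contact pathways with
the standard USEPA formulation

    ILCR_ing  = CS * CSF_ing  * (BW/70)^(1/3) * IR * EF * ED / (BW * AT * 1e6)
    ILCR_derm = CS * CSF_derm * (BW/70)^(1/3) * SA * AF * ABS * EF * ED / (BW * AT * 1e6)

where CS is the TEQ (ng/g; the 1e6 divisor converts ng to mg), CSF the BaP
carcinogenic slope factor of the pathway and the remaining factors the
usual exposure parameters.  The summed risk is banded as negligible
(< 1e-6), potential (1e-6 to 1e-4, inclusive) or high (> 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np

#: Toxic equivalency factors of the 16 priority PAHs relative to BaP.
DEFAULT_TEF: Dict[str, float] = {
    "NAP": 0.001,
    "ANY": 0.001,
    "ANA": 0.001,
    "FLU": 0.001,
    "PHE": 0.001,
    "ANT": 0.01,
    "FLT": 0.001,
    "PYR": 0.001,
    "BaA": 0.1,
    "CHR": 0.001,
    "BbF": 0.1,
    "BkF": 0.1,
    "BaP": 1.0,
    "IcdP": 0.1,
    "DBA": 1.0,
    "BPE": 0.01,
}

#: A representative coastal/urban congener composition (mass fractions of
#: the 16-congener sum).  Used to convert a simulated total-PAH sediment
#: field into TEQ when congener-resolved data are absent; synthetic, not a
#: measured profile.
DEFAULT_MIXTURE: Dict[str, float] = {
    "NAP": 0.12,
    "ANY": 0.02,
    "ANA": 0.02,
    "FLU": 0.04,
    "PHE": 0.15,
    "ANT": 0.03,
    "FLT": 0.13,
    "PYR": 0.11,
    "BaA": 0.06,
    "CHR": 0.08,
    "BbF": 0.07,
    "BkF": 0.03,
    "BaP": 0.05,
    "IcdP": 0.04,
    "DBA": 0.01,
    "BPE": 0.04,
}

BAND_NEGLIGIBLE = "negligible"
BAND_POTENTIAL = "potential"
BAND_HIGH = "high"

_THRESH_LOW = 1.0e-6
_THRESH_HIGH = 1.0e-4


def validate_tef(tef: Mapping[str, float]) -> None:
    if any(v <= 0 for v in tef.values()):
        raise ValueError("all TEF values must be positive")
    if abs(tef.get("BaP", 0.0) - 1.0) > 1e-12:
        raise ValueError("the BaP entry of a TEF table must equal 1")


def toxic_equivalent(
    conc: Mapping[str, float],
    tef: Optional[Mapping[str, float]] = None,
) -> float:
    """BaP toxic-equivalent concentration: sum C_i TEF_i (ng/g).

    Raises ``ValueError`` for negative concentrations or a congener name
    missing from the TEF table (the offending name is reported).
    """
    table = DEFAULT_TEF if tef is None else tef
    total = 0.0
    for name, c in conc.items():
        if name not in table:
            raise ValueError(f"unknown PAH congener {name!r} (no TEF entry)")
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}")
        total += c * table[name]
    return total


def mixture_teq_factor(
    mixture: Optional[Mapping[str, float]] = None,
    tef: Optional[Mapping[str, float]] = None,
) -> float:
    """TEQ per unit total-PAH concentration for a fixed congener mixture."""
    mix = DEFAULT_MIXTURE if mixture is None else mixture
    total = sum(mix.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"mixture fractions must sum to 1, got {total}")
    return toxic_equivalent(dict(mix), tef)


@dataclass
class ILCRParams:
    """Exposure parameters of the ILCR model (USEPA defaults for adults)."""

    EF: float = 350.0          # exposure frequency, d/y
    ED: float = 40.0           # exposure duration, y
    IR: float = 100.0          # sediment ingestion rate, mg/d
    SA: float = 5700.0         # dermal exposure area, cm^2/d
    AF: float = 0.07           # dermal adherence factor, mg/cm^2
    ABS: float = 0.13          # dermal absorption fraction
    AT: float = 70.0 * 365.0   # averaging time, d
    BW: float = 70.0           # body weight, kg
    CSF_ing: float = 7.3       # BaP slope factor, ingestion, (mg/(kg d))^-1
    CSF_derm: float = 3.85     # BaP slope factor, dermal, (mg/(kg d))^-1
    PEF: float = 1.36e9        # particle emission factor, m^3/kg (inhalation
    #                            pathway; carried for completeness, unused)

    def __post_init__(self) -> None:
        for name in ("EF", "ED", "IR", "SA", "AF", "AT", "BW", "CSF_ing", "CSF_derm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.ABS <= 1.0:
            raise ValueError("ABS must lie in (0, 1]")


def ilcr_ingestion(CS, p: ILCRParams):
    """Ingestion-pathway incremental lifetime cancer risk for TEQ ``CS`` (ng/g)."""
    CS = np.asarray(CS, dtype=float)
    if np.any(CS < 0):
        raise ValueError("CS must be >= 0")
    out = (
        CS * p.CSF_ing * (p.BW / 70.0) ** (1.0 / 3.0) * p.IR * p.EF * p.ED
        / (p.BW * p.AT * 1.0e6)
    )
    return out if out.ndim else float(out)


def ilcr_dermal(CS, p: ILCRParams):
    """Dermal-pathway incremental lifetime cancer risk for TEQ ``CS`` (ng/g)."""
    CS = np.asarray(CS, dtype=float)
    if np.any(CS < 0):
        raise ValueError("CS must be >= 0")
    out = (
        CS * p.CSF_derm * (p.BW / 70.0) ** (1.0 / 3.0)
        * p.SA * p.AF * p.ABS * p.EF * p.ED
        / (p.BW * p.AT * 1.0e6)
    )
    return out if out.ndim else float(out)


def classify_risk(ilcr_total: float) -> str:
    """Risk band: negligible (< 1e-6), potential ([1e-6, 1e-4]), high (> 1e-4)."""
    if ilcr_total < 0:
        raise ValueError("ILCR must be >= 0")
    if ilcr_total < _THRESH_LOW:
        return BAND_NEGLIGIBLE
    if ilcr_total <= _THRESH_HIGH:
        return BAND_POTENTIAL
    return BAND_HIGH


@dataclass
class RiskResult:
    """Per-location risk summary (scalar or field)."""

    teq: np.ndarray
    ilcr_ing: np.ndarray
    ilcr_derm: np.ndarray
    ilcr_total: np.ndarray
    band: np.ndarray           # array of band-name strings
    min_total: float
    max_total: float

    def band_counts(self) -> Dict[str, int]:
        names, counts = np.unique(self.band, return_counts=True)
        return {str(n): int(c) for n, c in zip(names, counts)}


def risk_map(
    teq_field: np.ndarray,
    p: ILCRParams,
    mask: Optional[np.ndarray] = None,
) -> RiskResult:
    """Cellwise ILCR (both pathways, their sum and band) over a TEQ field.

    ``mask`` (boolean, True = evaluate) restricts the map to sea cells;
    masked-out cells carry zero risk and the band "negligible".
    """
    teq = np.asarray(teq_field, dtype=float)
    if mask is None:
        mask = np.ones_like(teq, dtype=bool)
    if np.any(teq[mask] < 0):
        bad = np.argwhere(mask & (teq < 0))[0]
        raise ValueError(f"negative TEQ at cell {tuple(int(v) for v in bad)}")
    teq_eval = np.where(mask, teq, 0.0)
    ing = ilcr_ingestion(teq_eval, p)
    derm = ilcr_dermal(teq_eval, p)
    total = ing + derm
    band = np.where(
        total < _THRESH_LOW,
        BAND_NEGLIGIBLE,
        np.where(total <= _THRESH_HIGH, BAND_POTENTIAL, BAND_HIGH),
    )
    evaluated = total[mask]
    return RiskResult(
        teq=teq_eval,
        ilcr_ing=ing,
        ilcr_derm=derm,
        ilcr_total=total,
        band=band,
        min_total=float(evaluated.min()) if evaluated.size else 0.0,
        max_total=float(evaluated.max()) if evaluated.size else 0.0,
    )
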