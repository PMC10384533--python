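"""Model-fidelity statistics: Willmott skill score and equilibration times.

The skill score is the index of agreement

    Skill = 1 - sum |M_i - D_i|^2 / sum (|M_i - Dbar| + |D_i - Dbar|)^2

with M the modelled and D the observed series and Dbar the observed mean.
Skill is 1 exactly when the model matches the observations elementwise and
is rated on the conventional bands poor (< 0.2), medium (0.2-0.5), good
(0.5-0.7) and excellent (> 0.7); boundary values take the lower band.

Dynamic-equilibrium detection finds the earliest time from which a series'
window means stop drifting: tidal fluctuation is averaged out by choosing a
window of one or more tidal cycles, and equilibrium is declared when k
consecutive window-to-window changes are each below a relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .observations import ObsSeries


class UndefinedSkillError(ValueError):
    """Skill denominator is zero while the model-observation misfit is not."""


class InsufficientDataError(ValueError):
    """Series too short for the requested equilibration analysis."""


RATING_BANDS = (
    (0.2, "poor"),
    (0.5, "medium"),
    (0.7, "good"),
)


def skill_rating(skill: float) -> str:
    """Band name for a skill value; boundary values take the band below."""
    for upper, name in RATING_BANDS:
        if skill <= upper:
            return name
    return "excellent"


@dataclass
class SkillReport:
    skill: float
    rating: str
    n: int


def _wrap_degrees(delta: np.ndarray) -> np.ndarray:
    """Wrap angular differences into (-180, 180] degrees."""
    return (np.asarray(delta, float) + 180.0) % 360.0 - 180.0


def willmott_skill(
    M: Union[np.ndarray, ObsSeries],
    D: Union[np.ndarray, ObsSeries],
    angular: bool = False,
) -> SkillReport:
    """Willmott index of agreement between model M and observations D.

    ``angular=True`` compares flow-direction series on the circle: M is
    first replaced by D plus the wrapped angular difference so that, e.g.,
    359 deg vs 1 deg counts as a 2-degree misfit.

    Raises ``ValueError`` for fewer than 2 paired samples or unequal
    lengths, and :class:`UndefinedSkillError` when the denominator vanishes
    while the numerator does not.  The degenerate 0/0 case (M = D = const)
    scores 1 by convention.
    """
    m = np.asarray(M.values if isinstance(M, ObsSeries) else M, dtype=float)
    d = np.asarray(D.values if isinstance(D, ObsSeries) else D, dtype=float)
    if m.shape != d.shape or m.ndim != 1:
        raise ValueError("M and D must be 1-D arrays of equal length")
    n = len(m)
    if n < 2:
        raise ValueError("at least 2 paired samples are required")
    if angular:
        m = d + _wrap_degrees(m - d)
    dbar = d.mean()
    num = float(((m - d) ** 2).sum())
    den = float(((np.abs(m - dbar) + np.abs(d - dbar)) ** 2).sum())
    if den == 0.0:
        if num == 0.0:
            return SkillReport(skill=1.0, rating="excellent", n=n)
        raise UndefinedSkillError(
            "skill undefined: observations are constant but model differs"
        )
    skill = 1.0 - num / den
    return SkillReport(skill=skill, rating=skill_rating(skill), n=n)


def equilibration_time(
    series: ObsSeries,
    window: float,
    tol: float,
    k: int = 1,
) -> Optional[float]:
    """Earliest time at which the series reaches dynamic equilibrium.

    The series is cut into consecutive windows of ``window`` seconds from
    its first sample; equilibrium begins at the first window boundary from
    which ``k`` consecutive window-mean changes are each below ``tol``
    (relative to the preceding window mean).  Returns the boundary time in
    seconds, or ``None`` if the series never stabilizes.

    Raises :class:`InsufficientDataError` if fewer than k + 1 complete
    windows are available.
    """
    if window <= 0 or tol <= 0 or k < 1:
        raise ValueError("window and tol must be positive and k >= 1")
    t0 = series.times[0]
    idx = np.floor((series.times - t0) / window).astype(int)
    n_windows = int(idx.max())  # drop the (possibly partial) last window
    if n_windows < k + 1:
        raise InsufficientDataError(
            f"need at least {k + 1} complete windows, have {n_windows}"
        )
    means = np.array(
        [series.values[idx == q].mean() for q in range(n_windows)]
    )
    rel = np.abs(np.diff(means)) / np.maximum(np.abs(means[:-1]), 1.0e-300)
    stable = rel < tol  # stable[q-1] is the change into window q
    for q in range(1, n_windows - k + 1):
        if stable[q - 1 : q - 1 + k].all():
            return float(t0 + q * window)
    return None
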