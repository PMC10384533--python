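"""Idealized semi-closed narrow bay: rectilinear grid, bathymetry, mask, sources.

The real study system is a long, narrow, semi-enclosed tidal bay (depths
roughly 5-25 m) with a single open boundary at the mouth.  Here it is
idealized as a rectangular channel closed on three sides, with depth varying
linearly along the channel axis.  The rectilinear grid keeps every governing
equation intact (they are grid-metric independent at this level) while
remaining testable against closed-form channel solutions.

Conventions
-----------
Arrays are indexed ``[i, j]`` with ``i`` the along-channel index (``i = 0``
is the mouth column, ``i = nx - 1`` the head) and ``j`` the cross-channel
index.  The cell mask uses the integer codes :data:`LAND`, :data:`SEA`,
:data:`OPEN`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

LAND = 0
SEA = 1
OPEN = 2

MASK_NAMES = {LAND: "land", SEA: "sea", OPEN: "open_boundary"}


@dataclass
class BayGrid:
    """Rectilinear bay grid: geometry, bathymetry and land/sea/open mask.

    Parameters
    ----------
    nx, ny : int
        Cell counts along-channel and cross-channel.
    dx, dy : float
        Cell edge lengths (m).
    H : ndarray, shape (nx, ny)
        Still-water depth per cell (m); must be positive on wet cells.
    mask : ndarray of int, shape (nx, ny)
        Per-cell flag: LAND (0), SEA (1) or OPEN (2).  Open-boundary cells
        must lie on the grid perimeter.  Fully closed basins (no OPEN cell)
        are permitted and used for conservation testing.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    H: np.ndarray
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("dx and dy must be positive")
        if self.H.shape != (self.nx, self.ny):
            raise ValueError(f"H must have shape {(self.nx, self.ny)}, got {self.H.shape}")
        if self.mask.shape != (self.nx, self.ny):
            raise ValueError(f"mask must have shape {(self.nx, self.ny)}")
        if not np.isin(self.mask, [LAND, SEA, OPEN]).all():
            raise ValueError("mask entries must be LAND, SEA or OPEN")
        wet = self.mask != LAND
        if not (self.H[wet] > 0).all():
            raise ValueError("H must be > 0 on every sea and open-boundary cell")
        if not self._open_on_perimeter():
            raise ValueError("open-boundary cells must lie on the grid perimeter")

    def _open_on_perimeter(self) -> bool:
        oi, oj = np.nonzero(self.mask == OPEN)
        return bool(
            np.all((oi == 0) | (oi == self.nx - 1) | (oj == 0) | (oj == self.ny - 1))
        )

    @property
    def n_cells(self) -> int:
        """Total cell count nx*ny."""
        return self.nx * self.ny

    @property
    def area(self) -> float:
        """Horizontal area of one cell (m^2); uniform on a rectilinear grid."""
        return self.dx * self.dy

    @property
    def wet(self) -> np.ndarray:
        """Boolean (nx, ny): sea or open-boundary cells."""
        return self.mask != LAND

    @property
    def sea(self) -> np.ndarray:
        return self.mask == SEA

    @property
    def open(self) -> np.ndarray:
        return self.mask == OPEN

    @property
    def has_open_boundary(self) -> bool:
        return bool((self.mask == OPEN).any())

    def x_centers(self) -> np.ndarray:
        """Along-channel cell-center coordinates (m), mouth at x ~ dx/2."""
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy


def build_idealized_bay(
    nx: int,
    ny: int,
    length_m: float,
    width_m: float,
    depth_head_m: float,
    depth_mouth_m: float,
) -> BayGrid:
    """Build the idealized semi-closed bay: a rectangular channel, open at one end.

    The mouth occupies the full short side at ``i = 0`` (open boundary); the
    other three sides are closed coastline.  Depth varies linearly from
    ``depth_mouth_m`` at the mouth column to ``depth_head_m`` at the head
    column, uniform across the channel.

    Raises
    ------
    ValueError
        If any dimension or depth is non-positive, or nx/ny < 3.
    """
    if nx < 3 or ny < 3:
        raise ValueError("nx and ny must both be >= 3")
    if length_m <= 0 or width_m <= 0:
        raise ValueError("length_m and width_m must be positive")
    if depth_head_m <= 0 or depth_mouth_m <= 0:
        raise ValueError("depths must be positive")
    dx = length_m / nx
    dy = width_m / ny
    frac = np.arange(nx, dtype=float) / (nx - 1)
    col_depth = depth_mouth_m + (depth_head_m - depth_mouth_m) * frac
    H = np.repeat(col_depth[:, None], ny, axis=1)
    mask = np.full((nx, ny), SEA, dtype=np.int8)
    mask[0, :] = OPEN
    return BayGrid(nx=nx, ny=ny, dx=dx, dy=dy, H=H, mask=mask)


@dataclass
class SourceSet:
    """Shoreline discharge sources: ((i, j), Q) with Q a ΣPAHs mass rate in ng/s."""

    entries: Sequence[Tuple[Tuple[int, int], float]] = ()

    def validate(self, grid: BayGrid) -> None:
        for (i, j), q in self.entries:
            if q < 0:
                raise ValueError(f"source at ({i}, {j}) has negative rate {q}")
            if not (0 <= i < grid.nx and 0 <= j < grid.ny):
                raise ValueError(f"source cell ({i}, {j}) outside grid")
            if grid.mask[i, j] != SEA:
                raise ValueError(f"source cell ({i}, {j}) is not a sea cell")

    def rate_field(self, grid: BayGrid) -> np.ndarray:
        """Per-cell discharge rate (ng/s), shape (nx, ny)."""
        Q = np.zeros((grid.nx, grid.ny))
        for (i, j), q in self.entries:
            Q[i, j] += q
        return Q
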