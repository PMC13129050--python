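"""Shared grid containers.

All maps in one analysis live on a single :class:`GridSpec`: a planar,
row-major grid with origin at the lower-left corner.  Cells are half-open
``[x0 + j*s, x0 + (j+1)*s)`` along x and likewise along y, so every point
belongs to exactly one cell.  Coordinates are planar grid units (the
synthetic world does no geodesy); ``cell_area`` carries the nominal area
of one cell in km² so that range sizes can be reported in real units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "BinaryRangeMap", "SCENARIOS"]

#: Recognised climate scenarios: the present plus a moderate and a
#: business-as-usual warming trajectory.
SCENARIOS = ("current", "moderate", "business-as-usual")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared analysis grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be positive.
    cell_size
        Edge length of one cell in map units.
    origin
        ``(x0, y0)`` of the lower-left corner of the grid.
    cell_area
        Nominal area of one cell in km² (used by range-area summaries).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    cell_area: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of the full grid."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """Row/column indices of the cell(s) containing point(s) ``(x, y)``.

        Row 0 is the southernmost (lowest-y) row.  Points outside the grid
        raise ``ValueError``.
        """
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        if np.any((col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)):
            raise ValueError("point(s) outside the grid extent")
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of x and y centre coordinates, shaped like the grid."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class BinaryRangeMap:
    """A 0/1 presence grid for one species under one scenario."""

    presence: np.ndarray
    species_id: str
    scenario: str
    grid: GridSpec = field(repr=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if self.presence.shape != self.grid.shape:
            raise ValueError(
                f"presence shape {self.presence.shape} does not match "
                f"grid {self.grid.shape}"
            )
        vals = np.unique(self.presence)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("presence grid must contain only 0/1 values")
        self.presence = self.presence.astype(np.int8)
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )

    @property
    def n_cells(self) -> int:
        return int(self.presence.sum())


def check_same_grid(*specs: GridSpec) -> GridSpec:
    """Assert all maps share one GridSpec and return it."""
    first = specs[0]
    for other in specs[1:]:
        if other != first:
            raise ValueError("maps do not share a common GridSpec")
    return first
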