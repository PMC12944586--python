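"""In-memory containers for annual raster stacks.

Grids are north-up with a simple planar georeference: ``origin`` is the
(x, y) of the top-left corner in km and ``cell_size`` the square cell
edge.  Cell (r, c) has its centre at
``(x0 + (c + 0.5) s, y0 - (r + 0.5) s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterSeries", "LandUseSeries", "cell_centres"]


@dataclass
class RasterSeries:
    """A (n_years, rows, cols) float stack of annual grids."""

    stack: np.ndarray
    years: list[int]
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    nodata: float = np.nan
    labels: np.ndarray | None = None    # intended trend-class grid, if synthetic
    label_codes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3:
            raise ValueError("stack must be (n_years, rows, cols)")
        if self.stack.shape[0] != len(self.years):
            raise ValueError("band count does not match year list")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]


@dataclass
class LandUseSeries:
    """Annual integer class grids plus the code table that interprets them."""

    stack: np.ndarray
    years: list[int]
    class_table: dict[int, str]          # code -> {cropland, forest, shrubland, grassland, other}
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0

    def __post_init__(self):
        self.stack = np.asarray(self.stack)
        if not np.issubdtype(self.stack.dtype, np.integer):
            raise ValueError("land-use stack must be integer-coded")
        if self.stack.shape[0] != len(self.years):
            raise ValueError("band count does not match year list")
        present = set(np.unique(self.stack).tolist())
        unknown = present - set(self.class_table)
        if unknown:
            raise ValueError(f"codes {sorted(unknown)} missing from class table")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stack.shape[1:]

    def codes_for(self, *names: str) -> list[int]:
        """All codes whose class name is in ``names``."""
        return [c for c, n in self.class_table.items() if n in names]

    def grid(self, year: int) -> np.ndarray:
        return self.stack[self.years.index(year)]


def cell_centres(shape: tuple[int, int], origin=(0.0, 0.0), cell_size: float = 1.0):
    """(x, y) centre coordinate grids for a north-up raster."""
    rows, cols = shape
    x0, y0 = origin
    xs = x0 + (np.arange(cols) + 0.5) * cell_size
    ys = y0 - (np.arange(rows) + 0.5) * cell_size
    return np.meshgrid(xs, ys)
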