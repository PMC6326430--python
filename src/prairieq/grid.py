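"""Regular-grid data model shared by every raster in the pipeline.

All rasters live on a :class:`GridSpec`: a projected, north-up grid of square
cells (30 m by default, matching typical cropland-data-layer products).
Coordinates are Euclidean metres; there is no geographic (lat/lon) support.

Grid convention, stated once and used everywhere: row 0 is the top of the
map, indices are 0-based, and the centre of pixel ``(i, j)`` sits at
``origin + ((j + 0.5) * cell, -(i + 0.5) * cell)`` — i.e. ``origin`` is the
top-left *corner* of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "LandCoverGrid",
    "HabitatRaster",
    "QualityRaster",
    "GridAlignmentError",
]


class GridAlignmentError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid in projected metres.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both at least 1.
    cell_size
        Side length of a square cell in metres (default 30).
    origin
        ``(x, y)`` of the top-left corner of the grid.
    nodata_code
        Integer sentinel used for missing cells in integer rasters.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_code: int = -9999

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares."""
        return self.cell_size**2 / 10_000.0

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        x0, y0 = self.origin
        return (
            x0,
            y0 - self.n_rows * self.cell_size,
            x0 + self.n_cols * self.cell_size,
            y0,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of pixel-centre coordinates, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the pixel containing point (x, y); may be out of bounds."""
        x0, y0 = self.origin
        j = int(np.floor((x - x0) / self.cell_size))
        i = int(np.floor((y0 - y) / self.cell_size))
        return i, j

    def contains(self, x: float, y: float) -> bool:
        i, j = self.index_of(x, y)
        return 0 <= i < self.n_rows and 0 <= j < self.n_cols


def _check_shape(spec: GridSpec, arr: np.ndarray) -> None:
    if arr.shape != spec.shape:
        raise GridAlignmentError(
            f"array shape {arr.shape} does not match grid {spec.shape}"
        )


def require_aligned(*specs: GridSpec) -> None:
    """Raise :class:`GridAlignmentError` unless all specs describe one grid."""
    first = specs[0]
    for other in specs[1:]:
        if other != first:
            raise GridAlignmentError(f"grids differ: {first} vs {other}")


@dataclass
class LandCoverGrid:
    """Integer land-cover class codes on a grid, with a code → name legend.

    Class identity throughout the package is by *name* via the legend, never
    by numeric code, so synthetic and production legends interchange freely.
    Every non-nodata code must appear in the legend.
    """

    spec: GridSpec
    codes: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise TypeError("land-cover codes must be integers")
        _check_shape(self.spec, self.codes)
        present = set(np.unique(self.codes).tolist()) - {self.spec.nodata_code}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes missing from legend: {sorted(missing)}")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.codes == self.spec.nodata_code

    def code_for(self, class_name: str) -> int:
        for code, name in self.legend.items():
            if name == class_name:
                return code
        raise KeyError(f"class {class_name!r} not in legend")

    def class_mask(self, class_name: str) -> np.ndarray:
        """Boolean mask of pixels belonging to the named class."""
        return self.codes == self.code_for(class_name)

    def copy(self) -> "LandCoverGrid":
        return LandCoverGrid(self.spec, self.codes.copy(), dict(self.legend))


@dataclass
class HabitatRaster:
    """Baseline habitat suitability in [0, 1]; NaN marks nodata."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.spec, self.values)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("habitat suitability must lie in [0, 1]")


@dataclass
class QualityRaster:
    """Habitat quality in [0, 1] after threat degradation; NaN marks nodata."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.spec, self.values)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("habitat quality must lie in [0, 1]")
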