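"""Reclassification of land cover into suitability and threat rasters.

The baseline habitat layer assigns each land-cover class a suitability
weight H_j in [0, 1] (1.0 for native prairie and conservation grassland,
0.5 for small grains, 0.3 for fallow, 0 for non-habitat classes such as row
crops).  Threat layers are binary presence rasters built either by class
membership (cropland, woodland, urban), by buffering point facilities
(wells, turbines), or by rasterizing polygons (fields).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point
from shapely.prepared import prep
from shapely.strtree import STRtree

from .grid import GridSpec, HabitatRaster, LandCoverGrid

__all__ = [
    "SuitabilityTable",
    "reclassify_suitability",
    "reclassify_threat",
    "rasterize_buffered_points",
    "rasterize_polygons",
]

logger = logging.getLogger(__name__)


@dataclass
class SuitabilityTable:
    """Map land-cover class name → habitat suitability weight H_j in [0, 1].

    Classes absent from the table are non-habitat and default to 0.
    """

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, w in self.entries.items():
            if not 0.0 <= float(w) <= 1.0:
                raise ValueError(f"suitability for {name!r} out of [0, 1]: {w}")

    def weight(self, class_name: str) -> float:
        return float(self.entries.get(class_name, 0.0))


def reclassify_suitability(
    grid: LandCoverGrid, table: SuitabilityTable
) -> HabitatRaster:
    """Replace each pixel's class code with its suitability weight H_j.

    Nodata pixels become NaN.  Output depends only on class *names*, so any
    permutation of the numeric legend yields the same raster.
    """
    values = np.zeros(grid.spec.shape, dtype=float)
    for code, name in grid.legend.items():
        w = table.weight(name)
        if w != 0.0:
            values[grid.codes == code] = w
    values[grid.nodata_mask] = np.nan
    return HabitatRaster(grid.spec, values)


def reclassify_threat(grid: LandCoverGrid, threat_classes: set[str]) -> np.ndarray:
    """Binary raster: 1 where the pixel's class is in ``threat_classes``.

    Nodata pixels map to 0.  Unknown class names are a configuration error.
    """
    if not threat_classes:
        raise ValueError("threat_classes must be nonempty")
    known = set(grid.legend.values())
    unknown = set(threat_classes) - known
    if unknown:
        raise KeyError(f"threat classes not in legend: {sorted(unknown)}")
    out = np.zeros(grid.spec.shape, dtype=np.uint8)
    for name in threat_classes:
        out |= grid.class_mask(name).astype(np.uint8)
    return out


def rasterize_buffered_points(
    points: list[tuple[float, float]], radius: float, spec: GridSpec
) -> np.ndarray:
    """Binary raster: 1 where a pixel centre lies within ``radius`` of a point.

    A point always marks the pixel containing it (so a zero radius marks
    exactly that pixel, and the mask is monotone in radius).  Points outside
    the grid extent are kept (with a warning) and contribute wherever their
    buffer reaches pixel centres inside the window.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    out = np.zeros(spec.shape, dtype=np.uint8)
    if not points:
        return out
    cell = spec.cell_size
    x0, y0 = spec.origin
    for (px, py) in points:
        if not spec.contains(px, py):
            logger.warning("point (%s, %s) falls outside the grid extent", px, py)
        i, j = spec.index_of(px, py)
        if 0 <= i < spec.n_rows and 0 <= j < spec.n_cols:
            out[i, j] = 1
        if radius == 0:
            continue
        # candidate window of rows/cols whose centres could be within radius
        j_lo = max(0, int(np.floor((px - radius - x0) / cell - 0.5)))
        j_hi = min(spec.n_cols - 1, int(np.ceil((px + radius - x0) / cell - 0.5)))
        i_lo = max(0, int(np.floor((y0 - py - radius) / cell - 0.5)))
        i_hi = min(spec.n_rows - 1, int(np.ceil((y0 - py + radius) / cell - 0.5)))
        if j_lo > j_hi or i_lo > i_hi:
            continue
        xs = x0 + (np.arange(j_lo, j_hi + 1) + 0.5) * cell
        ys = y0 - (np.arange(i_lo, i_hi + 1) + 0.5) * cell
        dx2 = (xs - px) ** 2
        dy2 = (ys - py) ** 2
        within = dy2[:, None] + dx2[None, :] <= radius**2
        out[i_lo : i_hi + 1, j_lo : j_hi + 1] |= within.astype(np.uint8)
    return out


def rasterize_polygons(fields, spec: GridSpec) -> np.ndarray:
    """Label each pixel with the id of the polygon containing its centre.

    ``fields`` is an iterable of ``(id, shapely geometry)`` pairs (or any
    object with ``.id`` and ``.geometry``).  Pixels covered by no polygon get
    0; where polygons overlap, the highest id wins (documented tie-break).
    Ids must be positive integers.
    """
    pairs = []
    for f in fields:
        if hasattr(f, "id") and hasattr(f, "geometry"):
            pairs.append((int(f.id), f.geometry))
        else:
            fid, geom = f
            pairs.append((int(fid), geom))
    out = np.zeros(spec.shape, dtype=np.int32)
    if not pairs:
        return out
    for fid, geom in pairs:
        if fid <= 0:
            raise ValueError("polygon ids must be positive integers")
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for polygon id {fid}")

    X, Y = spec.cell_centers()
    centers = [Point(x, y) for x, y in zip(X.ravel(), Y.ravel())]
    tree = STRtree(centers)
    # ascending id order so the highest id overwrites on overlap
    for fid, geom in sorted(pairs, key=lambda p: p[0]):
        prepared = prep(geom)
        for k in tree.query(geom):
            if prepared.contains(centers[k]):
                out.flat[k] = fid
    return out
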