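"""Raster, vector and table I/O.

Rasters are read and written either as single-band TIFF (via :mod:`tifffile`,
with the grid geometry carried as JSON in the ImageDescription tag) or as
ESRI ASCII grid (``.asc``), a plain-text interchange format understood by
most GIS software.  Field polygons and threat points travel as GeoJSON;
survey stops and parameter tables as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .grid import GridSpec
from .scenarios import Field, FieldSet
from .validation import SurveyStop

__all__ = [
    "save_raster",
    "load_raster",
    "save_fields_geojson",
    "load_fields_geojson",
    "save_points_geojson",
    "load_points_geojson",
    "load_stops_csv",
    "save_stops_csv",
]


def save_raster(path: str | Path, spec: GridSpec, values: np.ndarray, nodata=None) -> None:
    """Write a raster as TIFF (.tif/.tiff) or ESRI ASCII grid (.asc)."""
    path = Path(path)
    values = np.asarray(values)
    if values.shape != spec.shape:
        raise ValueError("raster shape does not match grid spec")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        meta = {
            "cell_size": spec.cell_size,
            "origin": list(spec.origin),
            "nodata": nodata if nodata is None else float(nodata),
            "nodata_code": spec.nodata_code,
        }
        data = (
            values.astype(np.float32)
            if np.issubdtype(values.dtype, np.floating)
            else values.astype(np.int32)
        )
        tifffile.imwrite(path, data, description=json.dumps(meta))
    elif suffix == ".asc":
        _save_ascii_grid(path, spec, values, nodata)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


def _save_ascii_grid(path: Path, spec: GridSpec, values: np.ndarray, nodata) -> None:
    if nodata is None:
        nodata = spec.nodata_code
    x0, y0 = spec.origin
    yll = y0 - spec.n_rows * spec.cell_size
    is_float = np.issubdtype(values.dtype, np.floating)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {x0}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {spec.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        out = values.copy()
        if is_float:
            out = np.where(np.isfinite(out), out, float(nodata))
            np.savetxt(fh, out, fmt="%.6g")
        else:
            np.savetxt(fh, out, fmt="%d")


def load_raster(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read a raster written by :func:`save_raster`; NaN restored for nodata floats."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            desc = page.tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        spec = GridSpec(
            n_rows=values.shape[0],
            n_cols=values.shape[1],
            cell_size=float(meta.get("cell_size", 30.0)),
            origin=tuple(meta.get("origin", (0.0, 0.0))),
            nodata_code=int(meta.get("nodata_code", -9999)),
        )
        return spec, values
    if suffix == ".asc":
        return _load_ascii_grid(path)
    raise ValueError(f"unsupported raster format: {path.suffix!r}")


def _load_ascii_grid(path: Path) -> tuple[GridSpec, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999)
    values = np.loadtxt(lines[6:])
    values = values.reshape(n_rows, n_cols)
    if np.allclose(values, np.round(values)) and abs(values).max(initial=0) < 2**31:
        as_int = values.astype(np.int64)
        if np.array_equal(as_int, values):
            values = as_int.astype(np.int32)
    if np.issubdtype(values.dtype, np.floating):
        values[values == nodata] = np.nan
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    return (
        GridSpec(n_rows, n_cols, cell, origin, nodata_code=int(nodata)),
        values,
    )


def save_fields_geojson(path: str | Path, fields: FieldSet) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(f.geometry),
            "properties": {"id": f.id, "area_ha": f.area_ha, "class": f.land_class},
        }
        for f in fields.fields
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def load_fields_geojson(path: str | Path) -> FieldSet:
    doc = json.loads(Path(path).read_text())
    fields = [
        Field(
            id=int(feat["properties"]["id"]),
            geometry=shape(feat["geometry"]),
            area_ha=float(feat["properties"].get("area_ha", 0.0)),
            land_class=feat["properties"].get("class", "CRP grassland"),
        )
        for feat in doc["features"]
    ]
    return FieldSet(fields)


def save_points_geojson(path: str | Path, points: list[tuple[float, float]]) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": {},
        }
        for x, y in points
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def load_points_geojson(path: str | Path) -> list[tuple[float, float]]:
    doc = json.loads(Path(path).read_text())
    return [tuple(feat["geometry"]["coordinates"][:2]) for feat in doc["features"]]


def save_stops_csv(path: str | Path, stops: list[SurveyStop]) -> None:
    pd.DataFrame(
        {
            "id": [s.id for s in stops],
            "x": [s.x for s in stops],
            "y": [s.y for s in stops],
            "count": [s.count for s in stops],
        }
    ).to_csv(path, index=False)


def load_stops_csv(path: str | Path, buffer_radius: float = 400.0) -> list[SurveyStop]:
    df = pd.read_csv(path)
    return [
        SurveyStop(
            id=str(row["id"]),
            x=float(row["x"]),
            y=float(row["y"]),
            count=int(row.get("count", 0)),
            buffer_radius=buffer_radius,
        )
        for _, row in df.iterrows()
    ]
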