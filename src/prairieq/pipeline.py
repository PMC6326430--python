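"""End-to-end conveniences tying the pipeline stages together.

These helpers assemble the standard five threat layers (woodland, urban,
cropland, roads, energy) from a land-cover grid plus point/line threat
sources, and run land cover → suitability → degradation → quality in one
call.  They are what the CLI, the examples and the acceptance script use.
"""

from __future__ import annotations

import numpy as np

from .config import ParameterBundle
from .grid import HabitatRaster, LandCoverGrid, QualityRaster
from .landcover import rasterize_buffered_points, reclassify_suitability, reclassify_threat
from .quality import DegradationRaster, ThreatLayer, degradation, quality
from .synth import SyntheticLandscape

__all__ = ["build_threat_layers", "run_quality", "threats_for_landscape"]

# land-cover classes feeding each class-based threat
THREAT_CLASS_MAP: dict[str, set[str]] = {
    "woodland": {"woodland"},
    "urban": {"urban"},
    "cropland": {"row crop"},
}


def build_threat_layers(
    landcover: LandCoverGrid,
    params: ParameterBundle,
    wells: list[tuple[float, float]] | None = None,
    turbines: list[tuple[float, float]] | None = None,
    road_raster: np.ndarray | None = None,
) -> list[ThreatLayer]:
    """Assemble the five standard threat layers present in ``params``.

    Class-based threats (woodland, urban, cropland) come from the land-cover
    legend; roads from the supplied binary raster; energy from well points
    buffered by the well radius (100 m default) unioned with turbine points
    buffered by the turbine radius (30 m default).  Threats named in the
    config but absent from the inputs are skipped (an all-absent threat
    contributes nothing anyway).
    """
    spec = landcover.spec
    layers: list[ThreatLayer] = []
    for tspec in params.threats:
        if tspec.name in THREAT_CLASS_MAP:
            classes = THREAT_CLASS_MAP[tspec.name] & set(landcover.legend.values())
            if not classes:
                continue
            presence = reclassify_threat(landcover, classes)
        elif tspec.name == "roads":
            if road_raster is None:
                continue
            presence = np.asarray(road_raster, dtype=np.uint8)
        elif tspec.name == "energy":
            well_mask = rasterize_buffered_points(
                wells or [], params.well_buffer_m, spec
            )
            turbine_mask = rasterize_buffered_points(
                turbines or [], params.turbine_buffer_m, spec
            )
            presence = well_mask | turbine_mask
        else:
            continue
        layers.append(ThreatLayer(tspec, presence))
    return layers


def run_quality(
    landcover: LandCoverGrid,
    params: ParameterBundle,
    threats: list[ThreatLayer],
) -> tuple[HabitatRaster, DegradationRaster, QualityRaster]:
    """Suitability, degradation and quality rasters for one land-cover layer."""
    habitat = reclassify_suitability(landcover, params.suitability)
    degr = degradation(landcover, threats, params.sensitivity, params.quality)
    qual = quality(habitat, degr, params.quality)
    return habitat, degr, qual


def threats_for_landscape(
    scape: SyntheticLandscape, params: ParameterBundle
) -> list[ThreatLayer]:
    """Threat layers for a synthetic landscape draw."""
    return build_threat_layers(
        scape.landcover,
        params,
        wells=scape.wells,
        turbines=scape.turbines,
        road_raster=scape.road_raster,
    )
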