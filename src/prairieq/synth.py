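"""Synthetic landscapes, threats, survey stops and over-dispersed counts.

The generator emulates the statistical structure of a northern-prairie
agricultural mosaic so the whole pipeline runs without any downloaded data:

* a rectangular *field mosaic* built by recursive rectangle splitting with
  split lines snapped to cell boundaries (fields therefore cover whole
  pixels, giving exact polygon/raster agreement), each field drawing its
  land-cover class from configured proportions;
* *roads* as horizontal and vertical one-pixel lines at a fixed spacing;
* *oil/gas wells* from a clustered parent–offspring (Thomas) point process,
  mimicking the tight well clusters seen in producing basins;
* *wind turbines* on a jittered regular grid, mimicking wind-farm layout;
* *survey stops* placed uniformly with a minimum spacing; and
* *bird counts* drawn from a negative binomial whose log-mean is linear in
  the habitat-quality covariate: count_i ~ NB(mean mu_i = exp(b0 + b1*x_i),
  dispersion theta), variance mu + mu^2/theta.

All randomness flows from a single seed through named substreams
(landscape / wells / turbines / stops / counts), so stages can be
regenerated independently and runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from shapely.geometry import box

from .grid import GridSpec, LandCoverGrid
from .scenarios import Field, FieldSet

__all__ = [
    "DEFAULT_CLASS_PROPORTIONS",
    "LandscapeConfig",
    "CountModelConfig",
    "SyntheticLandscape",
    "generate_landscape",
    "generate_stops",
    "generate_counts",
]

# A field-mosaic composition typical of a row-crop-dominated prairie region:
# cropland is the majority land cover, grassland (native + conservation)
# roughly a third, with minor woodland, urban and water components.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "native prairie": 0.20,
    "CRP grassland": 0.10,
    "small grains": 0.10,
    "fallow": 0.03,
    "row crop": 0.45,
    "woodland": 0.05,
    "urban": 0.04,
    "water": 0.03,
}

DEFAULT_LEGEND: dict[int, str] = {
    1: "native prairie",
    2: "CRP grassland",
    3: "small grains",
    4: "fallow",
    5: "row crop",
    6: "woodland",
    7: "urban",
    8: "water",
}

_SUBSTREAMS = ("landscape", "wells", "turbines", "stops", "counts")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG derived from one master seed."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown substream {name!r}")
    idx = _SUBSTREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))[idx])


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator."""

    grid: GridSpec = dc_field(default_factory=lambda: GridSpec(200, 200))
    field_size_range: tuple[float, float] = (300.0, 1200.0)  # field side, m
    class_proportions: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    road_spacing: float = 1600.0  # m between road lines (~1-mile section roads)
    well_parent_intensity: float = 0.08  # well-cluster parents per km^2
    wells_per_cluster: float = 6.0  # mean offspring per parent
    well_cluster_radius: float = 300.0  # Gaussian cluster spread, m
    turbine_grid_spacing: float = 2400.0  # m between turbines in the farm grid
    turbine_jitter: float = 200.0  # uniform jitter applied to each turbine, m
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be nonnegative")
        lo, hi = self.field_size_range
        if not 0 < lo <= hi:
            raise ValueError("field_size_range must satisfy 0 < lo <= hi")


@dataclass
class CountModelConfig:
    """Negative binomial count generator: log mu = beta0 + beta1 * quality."""

    beta0: float = 1.0
    beta1: float = 1.76
    theta: float = 1.5  # dispersion; variance = mu + mu^2/theta
    n_stops: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("dispersion theta must be positive")
        if self.n_stops < 1:
            raise ValueError("n_stops must be at least 1")


@dataclass
class SyntheticLandscape:
    """Everything one landscape draw produces."""

    landcover: LandCoverGrid
    crp_fields: FieldSet
    field_labels: np.ndarray  # id raster for *all* mosaic fields
    wells: list[tuple[float, float]]
    turbines: list[tuple[float, float]]
    road_raster: np.ndarray
    config: LandscapeConfig


def _split_mosaic(
    rng: np.random.Generator, n_rows: int, n_cols: int, cell: float, max_side: float
) -> list[tuple[int, int, int, int]]:
    """Recursively split the grid into cell-aligned rectangles (i0, i1, j0, j1)."""
    max_cells = max(1, int(round(max_side / cell)))
    out: list[tuple[int, int, int, int]] = []
    stack = [(0, n_rows, 0, n_cols)]
    while stack:
        i0, i1, j0, j1 = stack.pop()
        h, w = i1 - i0, j1 - j0
        if max(h, w) <= max_cells or min(h, w) < 2:
            out.append((i0, i1, j0, j1))
            continue
        if h >= w:
            cut = i0 + int(rng.integers(max(1, int(0.3 * h)), max(2, int(0.7 * h) + 1)))
            cut = min(max(cut, i0 + 1), i1 - 1)
            stack.append((i0, cut, j0, j1))
            stack.append((cut, i1, j0, j1))
        else:
            cut = j0 + int(rng.integers(max(1, int(0.3 * w)), max(2, int(0.7 * w) + 1)))
            cut = min(max(cut, j0 + 1), j1 - 1)
            stack.append((i0, i1, j0, cut))
            stack.append((i0, i1, cut, j1))
    return out


def generate_landscape(config: LandscapeConfig | None = None) -> SyntheticLandscape:
    """Draw one synthetic landscape; deterministic under ``config.seed``."""
    config = config or LandscapeConfig()
    spec = config.grid
    rng = substream(config.seed, "landscape")
    cell = spec.cell_size
    x0, y0 = spec.origin

    rects = _split_mosaic(
        rng, spec.n_rows, spec.n_cols, cell, config.field_size_range[1]
    )
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    name_to_code = {name: code for code, name in DEFAULT_LEGEND.items()}

    codes = np.zeros(spec.shape, dtype=np.int32)
    labels = np.zeros(spec.shape, dtype=np.int32)
    crp: list[Field] = []
    for fid, (i0, i1, j0, j1) in enumerate(rects, start=1):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        codes[i0:i1, j0:j1] = name_to_code.get(cls, 0)
        labels[i0:i1, j0:j1] = fid
        if cls == "CRP grassland":
            geom = box(
                x0 + j0 * cell, y0 - i1 * cell, x0 + j1 * cell, y0 - i0 * cell
            )
            area_ha = (i1 - i0) * (j1 - j0) * spec.cell_area_ha
            crp.append(Field(id=fid, geometry=geom, area_ha=area_ha))

    # roads: one-pixel horizontal/vertical lines every road_spacing
    road = np.zeros(spec.shape, dtype=np.uint8)
    step = max(1, int(round(config.road_spacing / cell)))
    road[::step, :] = 1
    road[:, ::step] = 1

    # wells: Thomas cluster process
    wrng = substream(config.seed, "wells")
    xmin, ymin, xmax, ymax = spec.extent
    area_km2 = (xmax - xmin) * (ymax - ymin) / 1e6
    n_parents = wrng.poisson(config.well_parent_intensity * area_km2)
    wells: list[tuple[float, float]] = []
    for _ in range(n_parents):
        px = wrng.uniform(xmin, xmax)
        py = wrng.uniform(ymin, ymax)
        for _ in range(wrng.poisson(config.wells_per_cluster)):
            wx = px + wrng.normal(0.0, config.well_cluster_radius)
            wy = py + wrng.normal(0.0, config.well_cluster_radius)
            if xmin <= wx < xmax and ymin <= wy < ymax:
                wells.append((wx, wy))

    # turbines: jittered regular grid
    trng = substream(config.seed, "turbines")
    turbines: list[tuple[float, float]] = []
    sx = config.turbine_grid_spacing
    gx = np.arange(xmin + sx / 2, xmax, sx)
    gy = np.arange(ymin + sx / 2, ymax, sx)
    for tx in gx:
        for ty in gy:
            jx = tx + trng.uniform(-config.turbine_jitter, config.turbine_jitter)
            jy = ty + trng.uniform(-config.turbine_jitter, config.turbine_jitter)
            if xmin <= jx < xmax and ymin <= jy < ymax:
                turbines.append((jx, jy))

    landcover = LandCoverGrid(spec, codes, dict(DEFAULT_LEGEND))
    return SyntheticLandscape(
        landcover=landcover,
        crp_fields=FieldSet(crp),
        field_labels=labels,
        wells=wells,
        turbines=turbines,
        road_raster=road,
        config=config,
    )


def generate_stops(
    spec: GridSpec,
    n: int,
    min_spacing: float = 800.0,
    seed: int = 0,
    buffer_radius: float = 400.0,
    max_tries: int = 10_000,
) -> list[tuple[float, float]]:
    """Place ``n`` stops uniformly with pairwise distance >= ``min_spacing``.

    Deterministic under ``seed``.  Raises after bounded rejection retries when
    the spacing is infeasible for the extent.
    """
    xmin, ymin, xmax, ymax = spec.extent
    diag = np.hypot(xmax - xmin, ymax - ymin)
    if n > 1 and min_spacing > diag:
        raise ValueError("min_spacing exceeds the grid diagonal; placement infeasible")
    rng = substream(seed, "stops")
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} stops at spacing {min_spacing} m "
                f"after {max_tries} tries"
            )
        tries += 1
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if all(np.hypot(x - px, y - py) >= min_spacing for px, py in pts):
            pts.append((x, y))
    return pts


def generate_counts(
    covariate: np.ndarray, config: CountModelConfig | None = None
) -> np.ndarray:
    """Draw independent NB counts with log mean linear in the covariate."""
    config = config or CountModelConfig()
    x = np.asarray(covariate, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    rng = substream(config.seed, "counts")
    mu = np.exp(config.beta0 + config.beta1 * x)
    theta = config.theta
    # NB(mean mu, dispersion theta) == numpy's negative_binomial(n=theta,
    # p=theta/(theta+mu)); numpy accepts non-integer n.
    return rng.negative_binomial(theta, theta / (theta + mu)).astype(int)
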