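"""Threat-driven habitat degradation and the half-saturation quality model.

The model follows the habitat-quality formulation used in ecosystem-services
tools such as InVEST.  Each threat *r* is a binary presence raster with a
relative weight ``w_r`` and a maximum influence distance ``d_max``; its
impact on a focal pixel *x* decays linearly with pixel-centre distance:

    i_rxy = max(0, 1 - d_xy / d_max)

Total degradation at *x* sums, over threats and over every threat-occupied
pixel *y* within ``d_max``:

    D_x = sum_r sum_y (w_r / sum_r w_r) * r_y * i_rxy * beta_x * S_jr

where ``S_jr`` is the sensitivity of the land-cover class *j* at *x* to
threat *r* and ``beta_x`` is pixel accessibility (fixed at 1 here).
Degradation converts to quality through a half-saturation function

    Q_x = H_x * (1 - D_x^z / (D_x^z + k^z))

so quality equals half the baseline suitability H_x exactly where D_x = k.
D is left uncapped; the transform bounds Q regardless of how many threat
pixels accumulate.

The production path computes each threat's proximity sum by direct discrete
convolution with an exact truncated kernel; :func:`degradation_bruteforce`
evaluates the literal double sum and exists to verify the fast path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import GridSpec, HabitatRaster, LandCoverGrid, QualityRaster, require_aligned

__all__ = [
    "ThreatSpec",
    "ThreatLayer",
    "SensitivityTable",
    "QualityParams",
    "DegradationRaster",
    "decay_factor",
    "threat_kernel",
    "degradation",
    "degradation_bruteforce",
    "quality",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThreatSpec:
    """One threat: name, relative weight w_r in [0,1], max influence distance (m)."""

    name: str
    weight: float
    d_max: float
    decay: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"threat weight out of [0, 1]: {self.weight}")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.decay != "linear":
            raise ValueError(f"unsupported decay type: {self.decay!r}")


@dataclass
class ThreatLayer:
    """A threat's parameters plus its binary presence raster."""

    spec: ThreatSpec
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        vals = np.unique(self.presence)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("threat presence raster must be binary")


@dataclass
class SensitivityTable:
    """Map (land-cover class, threat name) → sensitivity S_jr in [0, 1].

    Missing pairs default to 0 (the class is insensitive to that threat).
    """

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, s in self.entries.items():
            if not 0.0 <= float(s) <= 1.0:
                raise ValueError(f"sensitivity {key} out of [0, 1]: {s}")

    def sensitivity(self, class_name: str, threat_name: str) -> float:
        return float(self.entries.get((class_name, threat_name), 0.0))


@dataclass(frozen=True)
class QualityParams:
    """Half-saturation constant k, exponent z, accessibility, habitat threshold."""

    half_saturation: float = 0.20
    exponent: float = 2.5
    accessibility: float = 1.0
    suitability_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.half_saturation <= 0:
            raise ValueError("half_saturation must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if not 0.0 < self.suitability_threshold <= 1.0:
            raise ValueError("suitability_threshold must lie in (0, 1]")


@dataclass
class DegradationRaster:
    """Accumulated threat exposure D_x >= 0 per pixel."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError("degradation shape does not match grid")
        if np.nanmin(self.values, initial=0.0) < -1e-12:
            raise ValueError("degradation must be nonnegative")


def decay_factor(d: float, spec: ThreatSpec) -> float:
    """Linear decay i = max(0, 1 - d/d_max); 1 at the threat, 0 at/beyond d_max."""
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return max(0.0, 1.0 - d / spec.d_max)


def threat_kernel(spec: ThreatSpec, cell_size: float) -> np.ndarray:
    """Exact discrete decay kernel on pixel-centre offsets, truncated at d_max.

    The (0, 0) tap is 1: a threat pixel degrades itself fully.
    """
    radius = int(np.ceil(spec.d_max / cell_size))
    offsets = np.arange(-radius, radius + 1)
    dist = cell_size * np.hypot(offsets[:, None], offsets[None, :])
    kernel = np.maximum(0.0, 1.0 - dist / spec.d_max)
    return kernel


def _sensitivity_raster(
    landcover: LandCoverGrid, sens: SensitivityTable, threat_name: str
) -> np.ndarray:
    out = np.zeros(landcover.spec.shape, dtype=float)
    for code, class_name in landcover.legend.items():
        s = sens.sensitivity(class_name, threat_name)
        if s != 0.0:
            out[landcover.codes == code] = s
    return out


def degradation(
    landcover: LandCoverGrid,
    threats: list[ThreatLayer],
    sens: SensitivityTable,
    params: QualityParams | None = None,
) -> DegradationRaster:
    """Per-pixel degradation from all threats (convolution fast path).

    Threat weights are self-normalized by their sum, so with a single threat
    D is invariant to rescaling w_r.  An empty threat list yields an all-zero
    raster with a logged warning.
    """
    params = params or QualityParams()
    spec = landcover.spec
    if not threats:
        logger.warning("no threat layers supplied; degradation is zero everywhere")
        return DegradationRaster(spec, np.zeros(spec.shape))
    w_sum = sum(t.spec.weight for t in threats)
    if w_sum <= 0:
        raise ValueError("threat weights must sum to a positive value")
    total = np.zeros(spec.shape, dtype=float)
    for layer in threats:
        if layer.presence.shape != spec.shape:
            raise ValueError(
                f"threat {layer.spec.name!r} presence not aligned with land cover"
            )
        kernel = threat_kernel(layer.spec, spec.cell_size)
        prox = ndimage.convolve(
            layer.presence.astype(float), kernel, mode="constant", cval=0.0
        )
        s_raster = _sensitivity_raster(landcover, sens, layer.spec.name)
        total += (layer.spec.weight / w_sum) * params.accessibility * s_raster * prox
    # convolution can leave tiny negative dust at exact zeros
    np.clip(total, 0.0, None, out=total)
    return DegradationRaster(spec, total)


def degradation_bruteforce(
    landcover: LandCoverGrid,
    threats: list[ThreatLayer],
    sens: SensitivityTable,
    params: QualityParams | None = None,
    max_dim: int = 128,
) -> DegradationRaster:
    """Literal evaluation of the degradation double sum; test oracle only.

    Iterates explicitly over every threat-occupied pixel and accumulates its
    decayed contribution at every focal pixel.  Refuses grids larger than
    ``max_dim`` on a side.
    """
    params = params or QualityParams()
    spec = landcover.spec
    if max(spec.shape) > max_dim:
        raise ValueError(f"brute-force oracle limited to {max_dim}x{max_dim} grids")
    if not threats:
        return DegradationRaster(spec, np.zeros(spec.shape))
    w_sum = sum(t.spec.weight for t in threats)
    if w_sum <= 0:
        raise ValueError("threat weights must sum to a positive value")
    rows = np.arange(spec.n_rows)[:, None]
    cols = np.arange(spec.n_cols)[None, :]
    total = np.zeros(spec.shape, dtype=float)
    for layer in threats:
        w_norm = layer.spec.weight / w_sum
        s_raster = _sensitivity_raster(landcover, sens, layer.spec.name)
        for (yi, yj) in np.argwhere(layer.presence == 1):
            d = spec.cell_size * np.hypot(rows - yi, cols - yj)
            decay = np.maximum(0.0, 1.0 - d / layer.spec.d_max)
            total += w_norm * params.accessibility * s_raster * decay
    return DegradationRaster(spec, total)


def quality(
    habitat: HabitatRaster,
    degr: DegradationRaster,
    params: QualityParams | None = None,
) -> QualityRaster:
    """Half-saturation transform: Q = H * (1 - D^z / (D^z + k^z))."""
    params = params or QualityParams()
    require_aligned(habitat.spec, degr.spec)
    k = params.half_saturation
    z = params.exponent
    dz = np.power(degr.values, z)
    q = habitat.values * (1.0 - dz / (dz + k**z))
    return QualityRaster(habitat.spec, q)
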