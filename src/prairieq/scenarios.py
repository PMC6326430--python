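"""Nested conservation-grassland conversion scenarios.

Conversion scenarios remove a fraction of conservation (CRP) grassland
*fields* — never individual pixels — and relabel them as row crop,
emulating a producer's field-by-field decision to leave a conservation
program.  A single random permutation of field ids drives every fraction:
the 10% subset is a prefix of the 25% subset, and so on, so scenarios are
nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import LandCoverGrid, require_aligned
from .landcover import rasterize_polygons

__all__ = [
    "Field",
    "FieldSet",
    "ScenarioSet",
    "DEFAULT_FRACTIONS",
    "draw_nested_subsets",
    "apply_conversion",
    "verify_converted_fraction",
]

DEFAULT_FRACTIONS = (0.10, 0.25, 0.50, 0.75, 1.00)


@dataclass
class Field:
    """One conservation-grassland field polygon."""

    id: int
    geometry: object
    area_ha: float = 0.0
    land_class: str = "CRP grassland"


@dataclass
class FieldSet:
    fields: list[Field] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.fields]
        if len(ids) != len(set(ids)):
            raise ValueError("field ids must be unique")

    def __len__(self) -> int:
        return len(self.fields)

    def ids(self) -> list[int]:
        return [f.id for f in self.fields]

    def by_id(self, fid: int) -> Field:
        for f in self.fields:
            if f.id == fid:
                return f
        raise KeyError(f"no field with id {fid}")


@dataclass
class ScenarioSet:
    """Nested subsets of field ids at increasing conversion fractions."""

    fractions: tuple[float, ...]
    subsets: dict[float, frozenset[int]]
    seed: int

    def __post_init__(self) -> None:
        ordered = sorted(self.fractions)
        for lo, hi in zip(ordered, ordered[1:]):
            if not self.subsets[lo] <= self.subsets[hi]:
                raise ValueError("scenario subsets must be nested")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def draw_nested_subsets(
    fields: FieldSet,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> ScenarioSet:
    """Draw one permutation of field ids; subset(f) is its first round(f*N) ids.

    Nesting across fractions holds by construction.  Subset sizes round
    half-up.  Duplicate fractions are a configuration error.
    """
    if len(set(fractions)) != len(fractions):
        raise ValueError("duplicate scenario fractions")
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction out of (0, 1]: {f}")
    if len(fields) < 1:
        raise ValueError("need at least one field")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(fields.ids()))
    n = len(order)
    subsets = {
        f: frozenset(int(i) for i in order[: _round_half_up(f * n)]) for f in fractions
    }
    return ScenarioSet(tuple(fractions), subsets, seed)


def apply_conversion(
    landcover: LandCoverGrid,
    fields: FieldSet,
    ids: frozenset[int] | set[int],
    target_class: str = "row crop",
    field_labels: np.ndarray | None = None,
) -> LandCoverGrid:
    """Relabel every pixel of the selected fields as ``target_class``.

    Conversion is whole-field: a pixel changes iff its field-id label is in
    ``ids``.  ``field_labels`` (from :func:`rasterize_polygons`) may be passed
    to avoid re-rasterizing; otherwise it is computed here.
    """
    target_code = landcover.code_for(target_class)
    known = set(fields.ids())
    stray = set(ids) - known
    if stray:
        raise KeyError(f"ids not in field set: {sorted(stray)}")
    out = landcover.copy()
    if not ids:
        return out
    if field_labels is None:
        field_labels = rasterize_polygons(
            [(f.id, f.geometry) for f in fields.fields], landcover.spec
        )
    mask = np.isin(field_labels, list(ids))
    out.codes[mask] = target_code
    return out


def verify_converted_fraction(
    base: LandCoverGrid,
    scenario: LandCoverGrid,
    crp_class: str = "CRP grassland",
) -> float:
    """Fraction of baseline conservation-grassland *area* no longer that class."""
    require_aligned(base.spec, scenario.spec)
    base_area = int(base.class_mask(crp_class).sum())
    if base_area == 0:
        raise ZeroDivisionError("baseline contains no conservation grassland")
    scen_area = int(scenario.class_mask(crp_class).sum())
    return (base_area - scen_area) / base_area
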