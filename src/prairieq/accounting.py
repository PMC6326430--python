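"""Lost / degraded / retained habitat accounting and regional summaries.

A pixel is *suitable* when its value meets the habitat threshold (0.3 by
default — the lowest weight assigned to any habitat class).  Comparing a
baseline raster with an impacted one, each baseline-suitable pixel is:

* ``lost``      — impacted value fell below the threshold;
* ``degraded``  — value fell but stayed at or above the threshold;
* ``retained``  — value did not fall (increases count as retained).

Pixels below the threshold at baseline are ``not_habitat``.  Regional
summaries convert pixel counts to hectares and derive loss/degradation
percentages against the baseline suitable area of the same region.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np
import pandas as pd

from .grid import HabitatRaster, QualityRaster, require_aligned

__all__ = [
    "ChangeCategory",
    "classify_change",
    "summarize_by_region",
    "percent_change",
]


class ChangeCategory(IntEnum):
    NOT_HABITAT = 0
    LOST = 1
    DEGRADED = 2
    RETAINED = 3


def classify_change(
    baseline: HabitatRaster | QualityRaster,
    impacted: QualityRaster,
    threshold: float = 0.3,
) -> np.ndarray:
    """Per-pixel change category (int8 array of :class:`ChangeCategory`).

    Nodata (NaN in either raster) maps to -1.
    """
    require_aligned(baseline.spec, impacted.spec)
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    b = baseline.values
    q = impacted.values
    out = np.full(b.shape, -1, dtype=np.int8)
    valid = np.isfinite(b) & np.isfinite(q)
    out[valid & (b < threshold)] = ChangeCategory.NOT_HABITAT
    suitable = valid & (b >= threshold)
    out[suitable & (q < threshold)] = ChangeCategory.LOST
    out[suitable & (q >= threshold) & (q < b)] = ChangeCategory.DEGRADED
    out[suitable & (q >= b)] = ChangeCategory.RETAINED
    return out


def summarize_by_region(
    change: np.ndarray,
    regions: np.ndarray,
    cell_area_ha: float,
    region_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Tally change categories per region into a table of areas (ha).

    ``regions`` is an integer raster of region labels (0 or negative = outside
    any region).  The result has one row per region plus a ``Total`` row, with
    baseline/lost/degraded/retained areas and percent lost / percent degraded
    relative to the region's baseline suitable area.
    """
    if change.shape != regions.shape:
        raise ValueError("change and region rasters must be aligned")
    labels = [int(r) for r in np.unique(regions) if r > 0]
    rows = []
    for label in labels:
        in_region = regions == label
        counts = {
            cat: int(np.sum(in_region & (change == cat))) for cat in ChangeCategory
        }
        baseline_ha = (
            counts[ChangeCategory.LOST]
            + counts[ChangeCategory.DEGRADED]
            + counts[ChangeCategory.RETAINED]
        ) * cell_area_ha
        lost_ha = counts[ChangeCategory.LOST] * cell_area_ha
        degr_ha = counts[ChangeCategory.DEGRADED] * cell_area_ha
        name = (region_names or {}).get(label, str(label))
        rows.append(
            {
                "region": name,
                "baseline_ha": baseline_ha,
                "lost_ha": lost_ha,
                "degraded_ha": degr_ha,
                "remaining_ha": baseline_ha - lost_ha,
                "pct_lost": 100.0 * lost_ha / baseline_ha if baseline_ha else np.nan,
                "pct_degraded": 100.0 * degr_ha / baseline_ha
                if baseline_ha
                else np.nan,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "region",
            "baseline_ha",
            "lost_ha",
            "degraded_ha",
            "remaining_ha",
            "pct_lost",
            "pct_degraded",
        ],
    )
    if len(df):
        total = df[["baseline_ha", "lost_ha", "degraded_ha", "remaining_ha"]].sum()
        df.loc[len(df)] = {
            "region": "Total",
            "baseline_ha": total["baseline_ha"],
            "lost_ha": total["lost_ha"],
            "degraded_ha": total["degraded_ha"],
            "remaining_ha": total["remaining_ha"],
            "pct_lost": 100.0 * total["lost_ha"] / total["baseline_ha"]
            if total["baseline_ha"]
            else np.nan,
            "pct_degraded": 100.0 * total["degraded_ha"] / total["baseline_ha"]
            if total["baseline_ha"]
            else np.nan,
        }
    return df


def percent_change(
    before: float, after: float, mode: str = "signed", digits: int = 1
) -> float:
    """Percent change of ``after`` relative to ``before``, rounded half-up.

    ``mode="signed"`` gives 100*(after-before)/before; ``"loss_magnitude"``
    its absolute value.  Rounding is decimal half-up (so 9.25 → 9.3 at one
    digit, 9 at zero digits), matching how summary tables are printed.
    """
    if before <= 0:
        raise ZeroDivisionError("percent change undefined for before <= 0")
    if mode not in ("signed", "loss_magnitude"):
        raise ValueError(f"unknown mode {mode!r}")
    pct = 100.0 * (after - before) / before
    if mode == "loss_magnitude":
        pct = abs(pct)
    scale = 10.0**digits
    sign = 1.0 if pct >= 0 else -1.0
    return sign * np.floor(abs(pct) * scale + 0.5) / scale
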