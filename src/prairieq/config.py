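"""YAML configuration loading, parameter validation, and run manifests.

One config file parameterizes every pipeline stage: the habitat/sensitivity
table, the threat table (weight, maximum influence distance, decay type),
the half-saturation quality parameters, point-buffer radii and the scenario
fractions.  All range invariants are checked at load time and violations
name the offending key.  A :class:`RunManifest` ties outputs to the config
hash, seeds and input digests for exact reproducibility.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .landcover import SuitabilityTable
from .quality import QualityParams, SensitivityTable, ThreatSpec

__all__ = [
    "ParameterBundle",
    "RunManifest",
    "load_config",
    "default_config_path",
    "reported_areas",
]

_DATA = resources.files("prairieq.data")


def default_config_path() -> Path:
    """Path to the packaged default configuration."""
    return Path(str(_DATA / "default_config.yaml"))


@dataclass
class ParameterBundle:
    """Validated parameters for one pipeline run."""

    suitability: SuitabilityTable
    sensitivity: SensitivityTable
    threats: list[ThreatSpec]
    quality: QualityParams
    scenario_fractions: tuple[float, ...]
    well_buffer_m: float
    turbine_buffer_m: float
    config_hash: str = ""

    def threat(self, name: str) -> ThreatSpec:
        for t in self.threats:
            if t.name == name:
                return t
        raise KeyError(f"no threat named {name!r}")


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path | None = None) -> ParameterBundle:
    """Load and validate a YAML config; ``None`` loads the packaged defaults.

    Relative table paths resolve against the config file's directory.
    Schema or range violations raise ``ValueError`` naming the offending key.
    """
    path = Path(path) if path is not None else default_config_path()
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")

    qdict = raw.get("quality", {})
    try:
        qual = QualityParams(
            half_saturation=float(qdict.get("half_saturation", 0.20)),
            exponent=float(qdict.get("exponent", 2.5)),
            accessibility=float(qdict.get("accessibility", 1.0)),
            suitability_threshold=float(qdict.get("suitability_threshold", 0.3)),
        )
    except ValueError as exc:
        raise ValueError(f"quality: {exc}") from exc

    buffers = raw.get("buffers", {})
    well_buf = float(buffers.get("well_m", 100.0))
    turbine_buf = float(buffers.get("turbine_m", 30.0))
    if well_buf < 0 or turbine_buf < 0:
        raise ValueError("buffers: radii must be nonnegative")

    fractions = tuple(float(f) for f in raw.get(
        "scenario_fractions", (0.10, 0.25, 0.50, 0.75, 1.00)
    ))
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"scenario_fractions: fraction out of (0, 1]: {f}")
    if len(set(fractions)) != len(fractions):
        raise ValueError("scenario_fractions: duplicate fractions")

    tables = raw.get("tables", {})
    base = path.parent
    hs_path = base / tables.get("habitat_sensitivity", "habitat_sensitivity.csv")
    th_path = base / tables.get("threats", "threats.csv")
    hs = _read_table(hs_path)
    th = _read_table(th_path)

    threat_names = [str(t) for t in th["threat"]]
    threats = []
    for _, row in th.iterrows():
        try:
            threats.append(
                ThreatSpec(
                    name=str(row["threat"]),
                    weight=float(row["weight"]),
                    d_max=float(row["max_distance_m"]),
                    decay=str(row.get("decay", "linear")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"threats[{row['threat']}]: {exc}") from exc

    try:
        suit = SuitabilityTable(
            {str(r["class"]): float(r["habitat"]) for _, r in hs.iterrows()}
        )
    except ValueError as exc:
        raise ValueError(f"habitat_sensitivity.habitat: {exc}") from exc
    sens_entries = {}
    for _, row in hs.iterrows():
        for name in threat_names:
            if name not in hs.columns:
                raise ValueError(
                    f"habitat_sensitivity: missing sensitivity column {name!r}"
                )
            sens_entries[(str(row["class"]), name)] = float(row[name])
    try:
        sens = SensitivityTable(sens_entries)
    except ValueError as exc:
        raise ValueError(f"habitat_sensitivity sensitivity: {exc}") from exc

    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    digest.update(hs_path.read_bytes())
    digest.update(th_path.read_bytes())
    return ParameterBundle(
        suitability=suit,
        sensitivity=sens,
        threats=threats,
        quality=qual,
        scenario_fractions=fractions,
        well_buffer_m=well_buf,
        turbine_buffer_m=turbine_buf,
        config_hash=digest.hexdigest(),
    )


def reported_areas() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published PPR habitat-area summaries shipped with the package.

    Returns ``(scenario_areas, threat_totals)``: regional suitable-habitat
    areas under nested conversion scenarios, and region-wide lost/degraded
    totals under three threat scenarios, with percentages as printed.
    """
    scen = pd.read_csv(str(_DATA / "ppr_scenario_areas.csv"), comment="#")
    thr = pd.read_csv(str(_DATA / "ppr_threat_totals.csv"), comment="#")
    return scen, thr


@dataclass
class RunManifest:
    """Provenance record written next to every pipeline output."""

    command: str
    config_hash: str
    seeds: dict[str, int] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    package_version: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _hash_file(Path(path))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))
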