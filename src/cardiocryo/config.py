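"""Run configuration: one document describing geometry, materials, boundaries,
protocol and solver discretisation.

Accepted formats: YAML (.yml/.yaml), JSON (.json) and TOML (.toml, read-only).
Keys mirror the dataclass field names; materials and Robin tables are nested
sections with per-region / per-label overrides.  ``load_config(dump_config(c))``
is the identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .geometry import ConfigurationError, GeometryConfig
from .materials import MaterialModel, default_materials
from .protocols import (DEFAULT_OBSERVATION_S, Schedule, make_scenario, validate)
from .solver import BoundarySpec, RefrigerantParams, RobinBC


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    materials: MaterialModel = field(default_factory=default_materials)
    boundaries: Optional[BoundarySpec] = None     # None -> variant defaults
    scenario: Optional[str] = "B1"
    schedule: Optional[Schedule] = None           # custom overrides scenario
    observation_s: float = DEFAULT_OBSERVATION_S
    dt: float = 0.1
    store_every: float = 1.0
    preset: str = "reduced"                       # reduced | paper
    output_dir: str = "runs"

    def resolved_schedule(self) -> Schedule:
        if self.schedule is not None:
            sched = self.schedule
        elif self.scenario is not None:
            sched = make_scenario(self.scenario, observation=self.observation_s)
        else:
            raise ConfigurationError("config needs either 'scenario' or 'schedule'")
        diags = validate(sched)
        if diags:
            raise ConfigurationError("; ".join(diags))
        return sched

    def resolved_boundaries(self) -> BoundarySpec:
        if self.boundaries is not None:
            return self.boundaries
        if self.geometry.variant == "wood_slab":
            return BoundarySpec.wood_defaults()
        return BoundarySpec.main_defaults()

    def resolved_geometry(self) -> GeometryConfig:
        return self.geometry.with_preset(self.preset)

    def to_dict(self) -> Dict[str, Any]:
        d: Dict[str, Any] = {
            "geometry": asdict(self.geometry),
            "materials": self.materials.to_dict(),
            "scenario": self.scenario,
            "schedule": self.schedule.to_dict() if self.schedule else None,
            "observation_s": self.observation_s,
            "dt": self.dt,
            "store_every": self.store_every,
            "preset": self.preset,
            "output_dir": self.output_dir,
        }
        if self.boundaries is not None:
            d["boundaries"] = {
                "robin": {k: asdict(v) for k, v in self.boundaries.robin.items()},
                "refrigerant": asdict(self.boundaries.refrigerant),
            }
        else:
            d["boundaries"] = None
        return d

    @classmethod
    def from_dict(cls, d: Dict[str, Any]) -> "RunConfig":
        try:
            geometry = GeometryConfig(**d.get("geometry", {}))
            materials = MaterialModel.from_dict(d.get("materials", {}))
            boundaries = None
            if d.get("boundaries"):
                b = d["boundaries"]
                boundaries = BoundarySpec(
                    robin={k: RobinBC(**v) for k, v in b.get("robin", {}).items()},
                    refrigerant=RefrigerantParams(**b.get("refrigerant", {})))
            schedule = Schedule.from_dict(d["schedule"]) if d.get("schedule") else None
            return cls(geometry=geometry, materials=materials, boundaries=boundaries,
                       scenario=d.get("scenario"), schedule=schedule,
                       observation_s=float(d.get("observation_s", DEFAULT_OBSERVATION_S)),
                       dt=float(d.get("dt", 0.1)),
                       store_every=float(d.get("store_every", 1.0)),
                       preset=d.get("preset", "reduced"),
                       output_dir=d.get("output_dir", "runs"))
        except (TypeError, ValueError, KeyError) as exc:
            raise ConfigurationError(f"invalid run configuration: {exc}") from exc

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML, JSON or TOML by file extension."""
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yml", ".yaml"):
        data = yaml.safe_load(text)
    elif p.suffix == ".json":
        data = json.loads(text)
    elif p.suffix == ".toml":
        import tomllib
        data = tomllib.loads(text)
    else:
        raise ConfigurationError(f"unknown config format {p.suffix!r}")
    if not isinstance(data, dict):
        raise ConfigurationError("config document must be a mapping")
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path) -> None:
    """Write a RunConfig as YAML or JSON (round-trips losslessly)."""
    p = Path(path)
    d = config.to_dict()
    if p.suffix in (".yml", ".yaml"):
        p.write_text(yaml.safe_dump(d, sort_keys=True))
    elif p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2, sort_keys=True))
    else:
        raise ConfigurationError(f"unsupported dump format {p.suffix!r}")
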