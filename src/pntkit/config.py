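"""Run configuration: a single YAML-serializable record for reproducible runs.

Defaults equal the published protocol values where one exists (stage
schedule, thermostat rate range midpoint, 300 K, dt = 0.001 ps, first atom
fixed, 24 units with a 10 A gap, 6 units per turn).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .chirality import CalphaChiralityParams
from .manipulator import IntegratorParams, SpringSchedule, ThermostatParams
from .structures import HelixParams, StructureError


@dataclasses.dataclass
class RunConfig:
    chirality: str = "L"
    n_units: int = 24
    gap: float = 10.0
    helix: HelixParams = dataclasses.field(default_factory=HelixParams)
    inner_offset: float = 2.0
    outer_offset: float = 2.0
    schedule: SpringSchedule = dataclasses.field(default_factory=SpringSchedule)
    thermostat: ThermostatParams = dataclasses.field(default_factory=ThermostatParams)
    integrator: IntegratorParams = dataclasses.field(default_factory=IntegratorParams)
    chirality_params: CalphaChiralityParams = dataclasses.field(
        default_factory=lambda: CalphaChiralityParams(window=24)
    )
    base_seed: int = 0
    out_dir: str = "out"

    def validate(self) -> None:
        if self.chirality not in ("L", "D"):
            raise StructureError("chirality must be 'L' or 'D'")
        if self.n_units < 1:
            raise StructureError("n_units must be >= 1")
        self.helix.validate()
        self.schedule.validate()
        self.thermostat.validate()
        self.integrator.validate()
        self.chirality_params.validate()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["integrator"]["fixed_atoms"] = list(self.integrator.fixed_atoms)
        d["schedule"]["stages"] = [list(s) for s in self.schedule.stages]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "helix" in d:
            d["helix"] = HelixParams(**d["helix"])
        if "schedule" in d:
            stages = [tuple(s) for s in d["schedule"]["stages"]]
            d["schedule"] = SpringSchedule(stages=stages)
        if "thermostat" in d:
            d["thermostat"] = ThermostatParams(**d["thermostat"])
        if "integrator" in d:
            integ = dict(d["integrator"])
            integ["fixed_atoms"] = tuple(integ.get("fixed_atoms", (1,)))
            d["integrator"] = IntegratorParams(**integ)
        if "chirality_params" in d:
            d["chirality_params"] = CalphaChiralityParams(**d["chirality_params"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
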