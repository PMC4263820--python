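"""Run configuration: one structured YAML file drives a whole analysis.

All defaults are embedded; :func:`dump_default_config` writes them out so a
run is fully reproducible from the config file alone.  Unknown keys are
rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fem import LoadSchedule, SolverSettings
from .geometry import JointGeometryParams
from .materials import TABLE_PRESETS, TissueMaterial

__all__ = ["ContactOptions", "OutputOptions", "RunConfig",
           "load_config", "dump_default_config"]


@dataclass
class ContactOptions:
    penalty_scale: float = 100.0
    seal_scale: float = 1e3
    drainage_switch: bool = True
    horn_attachment: str = "fixed"          # "fixed" | "spring"
    horn_effective_length: float = 35.0     # hoop tether length for "spring"


@dataclass
class OutputOptions:
    n_hold_outputs: int = 20
    first_hold_offset: float = 0.3
    snapshot_times: tuple = (1.0, 61.0, 601.0, 1201.0)


def _strict_dataclass(cls, d: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


@dataclass
class RunConfig:
    geometry: JointGeometryParams = field(default_factory=JointGeometryParams)
    schedule: LoadSchedule = field(default_factory=LoadSchedule)
    solver: SolverSettings = field(default_factory=SolverSettings)
    contact: ContactOptions = field(default_factory=ContactOptions)
    outputs: OutputOptions = field(default_factory=OutputOptions)
    materials: dict = field(default_factory=lambda: {
        name: TissueMaterial.from_dict(mat.to_dict())
        for name, mat in TABLE_PRESETS.items()})
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["materials"] = {k: m.to_dict() if isinstance(m, TissueMaterial) else m
                          for k, m in self.materials.items()}
        d["solver"]["must_points"] = list(self.solver.must_points)
        d["outputs"]["snapshot_times"] = list(self.outputs.snapshot_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kw = {}
        if "geometry" in d:
            kw["geometry"] = _strict_dataclass(JointGeometryParams, d["geometry"])
        if "schedule" in d:
            kw["schedule"] = _strict_dataclass(LoadSchedule, d["schedule"])
        if "solver" in d:
            sd = dict(d["solver"])
            if "must_points" in sd:
                sd["must_points"] = tuple(sd["must_points"])
            kw["solver"] = _strict_dataclass(SolverSettings, sd)
        if "contact" in d:
            kw["contact"] = _strict_dataclass(ContactOptions, d["contact"])
        if "outputs" in d:
            od = dict(d["outputs"])
            if "snapshot_times" in od:
                od["snapshot_times"] = tuple(od["snapshot_times"])
            kw["outputs"] = _strict_dataclass(OutputOptions, od)
        if "materials" in d:
            kw["materials"] = {k: TissueMaterial.from_dict(m)
                               for k, m in d["materials"].items()}
        if "seed" in d:
            kw["seed"] = int(d["seed"])
        return cls(**kw)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.from_dict(data)


def dump_default_config(path) -> None:
    RunConfig().save(path)
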