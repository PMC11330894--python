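"""Run configuration: schema-validated YAML/JSON driving reproducible runs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError
from .meshgen import GraftSpec, RootSpec
from .morphometry import default_parameters
from .params import AortaParameterSet


@dataclass
class RunConfig:
    """Everything needed to regenerate a model byte-identically."""

    arch_type: str = "I"
    parameters: dict[str, Any] = field(default_factory=dict)  # symbol overrides
    resolution: float = 6.0
    n_circumferential: int = 64
    with_root: bool = True
    shell_thickness: float | None = None      # mm
    graft: dict[str, Any] | None = None       # GraftSpec fields
    root: dict[str, Any] | None = None        # RootSpec fields
    descending_length: float | None = None    # cm
    output: str = "aorta"
    file_format: str = "stl"
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        data = (json.loads(path.read_text()) if path.suffix == ".json"
                else yaml.safe_load(path.read_text()))
        if not isinstance(data, dict):
            raise ParameterError(f"{path} does not contain a config mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.resolve_params()  # validate eagerly, before any geometry work
        if cfg.graft is not None:
            cfg.graft_spec()
        if cfg.root is not None:
            cfg.root_spec()
        return cfg

    def resolve_params(self) -> AortaParameterSet:
        base = default_parameters(self.arch_type)
        return base.with_overrides(**self.parameters) if self.parameters else base

    def graft_spec(self) -> GraftSpec | None:
        if self.graft is None:
            return None
        known = {f.name for f in fields(GraftSpec)}
        unknown = set(self.graft) - known
        if unknown:
            raise ParameterError(f"unknown graft key(s): {sorted(unknown)}")
        return GraftSpec(**self.graft)

    def root_spec(self) -> RootSpec | None:
        if self.root is None:
            return None
        known = {f.name for f in fields(RootSpec)}
        unknown = set(self.root) - known
        if unknown:
            raise ParameterError(f"unknown root key(s): {sorted(unknown)}")
        return RootSpec(**self.root)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())
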