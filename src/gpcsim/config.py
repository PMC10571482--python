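"""YAML configuration loading and the run manifest."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import yaml

from .power import ScenarioConfig
from .simulate import GeneratorConfig

__all__ = ["load_config", "dump_config", "RunManifest"]

_SECTIONS = {"generator", "scenario"}


def load_config(path) -> tuple[GeneratorConfig, ScenarioConfig]:
    """Load (generator, scenario) configs from a YAML file.

    An empty file yields full defaults.  Unknown sections or keys are hard
    errors so typos cannot silently fall back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)} (expected {sorted(_SECTIONS)})")
    gen = GeneratorConfig.from_dict(raw.get("generator") or {})
    scen = ScenarioConfig.from_dict(raw.get("scenario") or {})
    return gen, scen


def dump_config(gen: GeneratorConfig, scen: ScenarioConfig, path) -> None:
    """Write the fully resolved configuration back out (round-trips with load_config)."""
    Path(path).write_text(
        yaml.safe_dump(
            {"generator": gen.to_dict(), "scenario": scen.to_dict()}, sort_keys=False
        )
    )


@dataclass
class RunManifest:
    """Self-describing record of one run: resolved config, seed and outputs."""

    command: str
    master_seed: int
    generator: dict
    scenario: dict
    version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    outputs: list[str] = field(default_factory=list)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
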