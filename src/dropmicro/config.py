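"""Run configuration: one seed, paths, and nested per-stage parameter sections.

Every stochastic operation in the toolkit takes its seed from here (or from an
explicit function argument); a config round-trips through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"seed": self.seed, "paths": self.paths, "stages": self.stages},
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            paths=dict(raw.get("paths", {})),
            stages={k: dict(v) for k, v in (raw.get("stages") or {}).items()},
        )

    def stage(self, name: str) -> dict[str, Any]:
        return self.stages.setdefault(name, {})
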