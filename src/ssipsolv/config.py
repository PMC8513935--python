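"""Run configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import STANDARD_TEMPERATURE


@dataclass
class RunConfig:
    """Settings shared by the command-line tools."""

    temperature: float = STANDARD_TEMPERATURE  # K
    input_paths: list[str] = field(default_factory=list)
    solvents: list[str] = field(default_factory=list)
    output_format: str = "csv"  # csv | json
    verbosity: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_format not in ("csv", "json"):
            raise ValueError(f"output_format must be csv or json, got {self.output_format!r}")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))
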