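"""Pipeline configuration and run manifests.

All defaults are the thresholds the classification and profiling rules are
defined with: a 110-residue head window, the 50/90 group rule and the 65%
subgroup floor, genome-mode read filters 80/50, and contig-mode filters
86/95/55.  Every value can be overridden, and a config round-trips through
its flat TOML serialisation losslessly.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .abundance import FilterParams
from .grouping import GroupingThresholds


@dataclass
class PipelineConfig:
    head_length: int = 110
    group_min_identity: float = 50.0
    group_min_coverage: float = 90.0
    subgroup_min_identity: float = 65.0
    genome_min_identity: float = 80.0
    genome_min_aligned_pct: float = 50.0
    contig_min_identity: float = 86.0
    contig_min_aligned_pct: float = 95.0
    contig_min_covered_fraction: float = 55.0
    alpha: float = 0.01
    seed: int = 0

    def grouping_thresholds(self) -> GroupingThresholds:
        return GroupingThresholds(
            group_min_identity=self.group_min_identity,
            group_min_coverage=self.group_min_coverage,
            subgroup_min_identity=self.subgroup_min_identity,
        )

    def genome_filters(self) -> FilterParams:
        return FilterParams(
            min_identity=self.genome_min_identity,
            min_aligned_pct=self.genome_min_aligned_pct,
        )

    def contig_filters(self) -> FilterParams:
        return FilterParams(
            min_identity=self.contig_min_identity,
            min_aligned_pct=self.contig_min_aligned_pct,
            min_covered_fraction=self.contig_min_covered_fraction,
        )

    def to_toml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for f in fields(self):
                value = getattr(self, f.name)
                handle.write(f"{f.name} = {value}\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-identically."""

    command: str
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    seed: int = 0
    version: str = __version__
    started: str = ""
    finished: str = ""

    @classmethod
    def start(cls, command: str, config: PipelineConfig, inputs: list[Path]) -> "RunManifest":
        return cls(
            command=command,
            config=asdict(config),
            inputs={str(p): _sha256(p) for p in inputs},
            seed=config.seed,
            started=datetime.now(timezone.utc).isoformat(),
        )

    def finish(self, outputs: list[Path]) -> None:
        self.outputs = {str(p): _sha256(p) for p in outputs}
        self.finished = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2)
            handle.write("\n")
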