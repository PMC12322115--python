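"""Run configuration, deterministic child seeds and provenance records.

A single global seed is carried in the config; every stochastic stage derives
its own child seed deterministically from it, so a run is reproducible from
the config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented range."""


def derive_seed(seed: int, label: str) -> int:
    """Deterministic child seed for a named stage, below 2**31."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Thresholds and defaults for every pipeline stage."""

    seed: int = 0

    # variant presence rule
    min_alt: int = 3
    min_vaf: float = 0.02

    # longitudinal drug test
    p_cut: float = 0.1
    lfc_cut: float = 0.2
    shift_method: str = "paired_t"  # or "wilcoxon_signed_rank"

    # signature learning
    top_k: int = 100
    grid_hidden: list = field(default_factory=lambda: [[64], [32, 16]])
    grid_dropout: list = field(default_factory=lambda: [0.0])
    grid_l2: list = field(default_factory=lambda: [1e-3])
    grid_epochs: list = field(default_factory=lambda: [150])
    folds: int = 3

    # enrichment
    gsea_permutations: int = 1000
    gsea_weight: float = 1.0
    ssgsea_alpha: float = 0.25

    # single-cell QC
    mito_max: float = 0.30
    feat_min: int = 200
    feat_max: int = 6000

    # survival
    horizon_months: float = 60.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.min_alt < 1:
            raise ConfigError("min_alt must be >= 1")
        if not 0 <= self.min_vaf < 1:
            raise ConfigError("min_vaf must be in [0, 1)")
        if not 0 < self.p_cut <= 1:
            raise ConfigError("p_cut must be in (0, 1]")
        if self.lfc_cut < 0:
            raise ConfigError("lfc_cut must be >= 0")
        if self.shift_method not in ("paired_t", "wilcoxon_signed_rank"):
            raise ConfigError(f"unknown shift_method {self.shift_method!r}")
        if self.top_k <= 0:
            raise ConfigError("top_k must be positive")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if not (self.grid_hidden and self.grid_dropout and self.grid_l2
                and self.grid_epochs):
            raise ConfigError("grid dimensions must be non-empty")
        if self.gsea_permutations < 1:
            raise ConfigError("gsea_permutations must be >= 1")
        if not 0 < self.mito_max < 1:
            raise ConfigError("mito_max must be in (0, 1)")
        if not 0 < self.feat_min < self.feat_max:
            raise ConfigError("require 0 < feat_min < feat_max")
        if self.horizon_months <= 0:
            raise ConfigError("horizon_months must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        canonical = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def write_provenance(out_dir: str | Path, config: RunConfig,
                     stage: str, **extra) -> Path:
    """Write a JSON provenance record sufficient to reproduce a run."""
    from evopharm import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        **extra,
    }
    path = out_dir / f"provenance_{stage}.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
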