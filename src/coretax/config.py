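"""Pipeline configuration.

Every stage parameter of the species-delimitation pipeline lives here, with
the published defaults: n=30 seed genomes, k=25 for candidate selection,
p=95% single-copy presence for definitive SCGs, 94% CNI clustering cutoff,
>90% completeness / <10% redundancy genome QC, 1% gap trimming and 100
top SCGs for the phylogeny supermatrix.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PipelineConfig:
    n_seed: int = 30
    k_candidate: int = 25
    p_final: float = 95.0            # percent of genomes with exactly one copy
    cni_cutoff: float = 0.94         # species cutoff, fraction
    completeness_min: float = 0.90   # strict >
    redundancy_max: float = 0.10     # strict <
    mcl_inflation: float = 1.5
    trim_gap_max: float = 0.01       # strict > drops the column
    top_scg_count: int = 100
    rng_seed: int = 17
    # scoring knobs (performance guardrails; see docs/methods.md)
    bit_floor: float = 25.0          # all-vs-all protein search reporting floor, bits
    score_floor: float = 0.0         # profile hit reporting floor, bits
    kmer_prefilter: bool = True
    prefilter_k: int = 5
    aligner: str = "star"            # "star" (built-in) or "mafft" (external adapter)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fracs = {
            "cni_cutoff": self.cni_cutoff,
            "completeness_min": self.completeness_min,
            "redundancy_max": self.redundancy_max,
            "trim_gap_max": self.trim_gap_max,
        }
        for name, v in fracs.items():
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if not 0 < self.p_final < 100:
            raise ConfigError(f"p_final is a percentage in (0, 100), got {self.p_final}")
        if self.k_candidate < 1:
            raise ConfigError("k_candidate must be >= 1")
        if self.n_seed < self.k_candidate:
            raise ConfigError(
                f"n_seed ({self.n_seed}) must be >= k_candidate ({self.k_candidate})")
        if self.mcl_inflation <= 1:
            raise ConfigError("mcl_inflation must be > 1")
        if self.top_scg_count < 1:
            raise ConfigError("top_scg_count must be >= 1")
        if self.aligner not in ("star", "mafft"):
            raise ConfigError(f"unknown aligner {self.aligner!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
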