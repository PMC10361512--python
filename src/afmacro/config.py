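"""Pipeline configuration: one place where every filter and count is stated.

A single config governs all stages so the detection thresholds (D_min,
A_cutoff), the occupancy and mean-frequency cutoffs, and the resampling
counts are declared once and recorded in every stage's run log.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cohort import CohortSpec

__all__ = ["PipelineConfig"]


@dataclasses.dataclass
class PipelineConfig:
    d_min: int = 20
    a_cutoff: int = 10
    min_occupancy: float = 0.35
    fbar_max: float = 0.35
    n_bootstrap: int = 10_000
    n_permutations: int = 10_000
    seed: int = 0
    n_species: int = 1
    include_zeros: bool = True
    cohort: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.d_min < 1 or self.a_cutoff < 1:
            raise ValueError("detection thresholds must be >= 1")
        if not 0 < self.min_occupancy <= 1:
            raise ValueError("min_occupancy must lie in (0, 1]")
        if not 0 < self.fbar_max <= 1:
            raise ValueError("fbar_max must lie in (0, 1]")
        if self.n_bootstrap < 1 or self.n_permutations < 1:
            raise ValueError("resampling counts must be positive")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")

    def cohort_spec(self) -> CohortSpec:
        """Materialize the synthetic-cohort spec, sharing the filter thresholds."""
        kwargs = dict(self.cohort)
        kwargs.setdefault("d_min", self.d_min)
        kwargs.setdefault("a_cutoff", self.a_cutoff)
        return CohortSpec(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
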