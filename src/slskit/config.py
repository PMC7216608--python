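"""Pipeline configuration loaded from YAML or JSON."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .synthetic import CohortConfig
from .validity import DEFAULT_CUTOFFS


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible end-to-end run needs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS
    ndigits: int = 2
    write_trajectory_files: bool = False
    verbosity: str = "INFO"

    def __post_init__(self):
        cutoffs = tuple(float(c) for c in self.cutoffs)
        if not cutoffs:
            raise ValueError("cutoff grid must be non-empty")
        if any(c <= 0 for c in cutoffs):
            raise ValueError("cutoffs must be positive")
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
            raise ValueError("cutoff grid must be strictly increasing")
        object.__setattr__(self, "cutoffs", cutoffs)
        if self.ndigits < 0:
            raise ValueError("ndigits must be >= 0")

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["legs"] = list(self.cohort.legs)
        d["cutoffs"] = list(self.cutoffs)
        return d

    def config_hash(self) -> str:
        """Stable hash of the full configuration (for run logging)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file.

    ``seed``, if given, overrides the seed in the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, seed=seed)


def config_from_dict(raw: dict, seed: int | None = None) -> PipelineConfig:
    cohort_raw = dict(raw.get("cohort", {}))
    if seed is not None:
        cohort_raw["seed"] = int(seed)
    cohort = CohortConfig(**cohort_raw)
    kwargs = {k: v for k, v in raw.items() if k != "cohort"}
    return PipelineConfig(cohort=cohort, **kwargs)
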