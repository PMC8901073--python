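"""Pipeline configuration: one object holding every tunable constant.

Defaults mirror the study protocol the package implements: Phred threshold
19 with at most 3 consecutive low-quality calls and a 0.75 retained-length
fraction for read QC; OTUs kept with total count >= 10 in >= 2 samples; CSS
at the median quantile scaled to 1000; a 90% prevalence core; 999 PERMANOVA
permutations; 1000 bootstrap replicates; alpha = 0.05.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from the root seed.

    Each pipeline stage draws from its own substream so stages can be
    reordered or skipped without perturbing each other's randomness.
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclass
class PipelineConfig:
    seed: int = 42
    # read QC
    quality_threshold: int = 19
    max_bad_run: int = 3
    min_fraction: float = 0.75
    # OTU filter
    min_total: int = 10
    min_samples: int = 2
    # CSS normalization
    css_quantile: float = 0.5
    css_scale: float = 1000.0
    # core microbiome
    core_prevalence: float = 0.9
    # inference
    n_permutations: int = 999
    n_bootstrap: int = 1000
    significance_alpha: float = 0.05
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("min_fraction", "css_quantile", "core_prevalence",
                     "significance_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("quality_threshold", "max_bad_run", "min_total",
                     "min_samples", "n_permutations", "n_bootstrap"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.css_scale <= 0:
            raise ValueError("css_scale must be positive")

    def rng(self, stage: str) -> np.random.Generator:
        return substream(self.seed, stage)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
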