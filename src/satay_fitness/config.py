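"""Run configuration: every constant of the analysis surfaced in one place.

The defaults are the published values of the method; running with a default
``RunConfig`` reproduces the canonical pipeline. Any field can be overridden
per run, from the CLI or from a TOML config file.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    #: fraction of a coding region excluded at each gene end (central 80% kept)
    edge_fraction: float = 0.10
    #: outlier threshold multiplier on the percentile range
    outlier_multiplier: float = 1.5
    #: percentile pair defining the trimming range
    percentile_low: float = 5.0
    percentile_high: float = 95.0
    #: minimum usable sites after trimming for a determined fitness
    min_usable_sites: int = 5
    #: minimum expected insertions E(X) for cross-dataset comparisons
    min_expected_insertions: int = 5
    #: distance beyond which the insertion rate is held constant (bp)
    r_cut: int = 200_000
    #: range of the cumulative-curve polynomial fit (bp)
    fit_range: int = 400_000
    #: grid step of the cumulative insertion curve (bp)
    grid_step: int = 1_000
    #: generations of library expansion (generation-scaled fitness exponent)
    t_gen: float = 10.0
    #: replicate matching window (bp)
    match_window: int = 2
    #: impute unobserved (zero-read) insertion sites before averaging
    impute: bool = True
    #: include imputed zeros in the per-gene sample variance
    zeros_in_variance: bool = True
    #: count observed insertions for imputation over the full gene (True) or
    #: over the central region only (False)
    impute_full_gene: bool = True
    #: random seed for any stochastic step (subsampling, simulation)
    seed: int = 0

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Load a config from a TOML file; unknown keys are an error."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def header_lines(self) -> list[str]:
        """Config echo written as comments into output tables."""
        return [f"# {k}={v}" for k, v in sorted(self.as_dict().items())]
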