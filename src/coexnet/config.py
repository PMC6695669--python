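"""Analysis configuration with validated defaults.

The consensus cutoff presets come from the study design this pipeline
packages: 0.90 for the AD cohort and 0.96 for the PD cohort, on the
rank-normalized consensus scale (see docs/methods.md).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

CONSENSUS_CUTOFF_PRESETS = {"AD": 0.90, "PD": 0.96}


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    consensus_cutoff: float = 0.90
    de_alpha: float = 0.05
    de_use_adjusted: bool = False
    mi_bins: int | str = "auto"
    ensemble_trees: int = 100
    seed: int = 0
    community_resolution: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.consensus_cutoff <= 1.0:
            raise ConfigError(f"consensus_cutoff must be in [0, 1], got {self.consensus_cutoff}")
        if not 0.0 < self.de_alpha < 1.0:
            raise ConfigError(f"de_alpha must be in (0, 1), got {self.de_alpha}")
        if self.mi_bins != "auto":
            if int(self.mi_bins) < 2:
                raise ConfigError(f"mi_bins must be >= 2 or 'auto', got {self.mi_bins}")
            self.mi_bins = int(self.mi_bins)
        if int(self.ensemble_trees) < 1:
            raise ConfigError(f"ensemble_trees must be positive, got {self.ensemble_trees}")
        if float(self.community_resolution) <= 0:
            raise ConfigError(f"community_resolution must be positive, got {self.community_resolution}")
        self.seed = int(self.seed)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**json.loads(Path(path).read_text()))

    @classmethod
    def for_disease(cls, disease: str, **kwargs) -> "AnalysisConfig":
        kwargs.setdefault("consensus_cutoff", CONSENSUS_CUTOFF_PRESETS[disease.upper()])
        return cls(**kwargs)
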