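"""Run configuration: every threshold the pipeline applies, in one place.

Defaults mirror the study conditions: 1.5-fold expression change at
adjusted p < 0.05 with a 1 RPKM floor; ±2 kb TSS windows; ±10 kb
peak-center windows; tags-per-10-million signal scaling; 10 kb Hi-C bins
extracted with a 25 kb window. A config file is a flat YAML mapping; an
unknown key is an error so a typo can never silently change a threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

RP10M_SCALE = 10_000_000


@dataclass(frozen=True)
class AnalysisConfig:
    fc_threshold: float = 1.5       # expression fold-change cutoff (ratio)
    min_expression: float = 1.0     # RPKM floor; below it genes are not tested
    alpha: float = 0.05             # adjusted-p cutoff
    tss_half_window: int = 2000     # bp; promoter / TSS-accessibility window
    peak_half_window: int = 10000   # bp; heatmap window around peak centers
    rp10m_scale: int = RP10M_SCALE  # tags-per-10-million normalization constant
    hic_resolution: int = 10000     # bp; Hi-C anchor bin size
    hic_window: int = 25000         # bp; window used when interactions were extracted
    distal_filter: bool = True      # drop enhancer candidates near a TSS
    distal_min_tss_distance: int = 2000  # bp; "near" for the distal filter

    def __post_init__(self):
        positive = (
            "fc_threshold", "min_expression", "alpha", "tss_half_window",
            "peak_half_window", "rp10m_scale", "hic_resolution", "hic_window",
            "distal_min_tss_distance",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise ConfigError("fc_threshold must be > 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must be a flat mapping")
        return cls.from_dict(data)
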