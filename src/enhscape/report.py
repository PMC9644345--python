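"""Reporting helpers: percentage formatting and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from . import __version__
from .config import AnalysisConfig

__all__ = ["report_percent", "RunManifest", "StageTimer"]


def report_percent(numerator: int, denominator: int, decimals: int = 0):
    """100*n/d rounded half-up to ``decimals``; None (NA) when d == 0.

    Half-up rounding matches how the headline fractions are quoted
    (e.g. 1385/2022 -> 68 at zero decimals) and never depends on the
    platform's banker's rounding.
    """
    if numerator < 0 or denominator < 0:
        raise ValueError("counts must be >= 0")
    if denominator == 0:
        return None
    quant = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quant, rounding=ROUND_HALF_UP
    )
    return float(value)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageTimer:
    """Wall-clock stage timings for the manifest."""

    def __init__(self):
        self.timings: dict[str, float] = {}
        self._start: dict[str, float] = {}

    def start(self, stage: str) -> None:
        self._start[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.timings[stage] = round(time.perf_counter() - self._start.pop(stage), 4)


@dataclasses.dataclass
class RunManifest:
    """Snapshot of everything that determined a run's outputs.

    Re-running with the same inputs, config and seed reproduces identical
    analytic outputs; only the timings differ between runs.
    """

    config: AnalysisConfig
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    seed: int | None = None
    timings: dict[str, float] = dataclasses.field(default_factory=dict)

    def add_input(self, role: str, path: str | Path) -> None:
        self.inputs[role] = f"{path}:sha256:{_sha256(path)}"

    def write(self, path: str | Path) -> None:
        payload = {
            "tool": "enhscape",
            "version": __version__,
            "seed": self.seed,
            "config": self.config.to_dict(),
            "inputs": dict(sorted(self.inputs.items())),
            "timings": self.timings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
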