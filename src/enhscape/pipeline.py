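"""End-to-end orchestration: simulate -> DE -> TSS accessibility ->
enhancer calling/classification -> report -> loop nomination.

Each stage is independently usable from the library; this module wires
them together, applies the replicate-reproducibility rule at the track
boundary, and writes the output tables plus a run manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .config import AnalysisConfig
from .de import DEResult, differential_expression, write_de_table
from .enhancers import (
    EnhancerCall,
    LandscapeReport,
    TSSAccessibilityChange,
    attach_de_status,
    build_report,
    call_enhancers,
    classify_modality,
    tss_accessibility_table,
    write_calls_bed,
    write_changes_tsv,
    write_report,
)
from .intervals import IntervalSet, TSSRecord, replicate_reproducible
from .io import read_bed, read_bedpe, read_expression, read_tss_table
from .loops import nominate_candidates, write_candidates_tsv
from .report import RunManifest, StageTimer
from .simulate import SimulationParams, SyntheticStudy, simulate_study

log = logging.getLogger(__name__)

__all__ = [
    "LandscapeResult",
    "load_track",
    "run_landscape",
    "run_study_landscape",
    "modality_recovery",
    "run_en7_nomination",
    "run_pipeline",
]


@dataclass
class LandscapeResult:
    de: list[DEResult]
    changes: list[TSSAccessibilityChange]
    calls: list[EnhancerCall]
    report: LandscapeReport


def load_track(paths: Sequence[str | Path], label: str = "") -> IntervalSet:
    """Read one peak track, applying the both-replicates rule if two
    replicate files are given."""
    sets = [read_bed(p, label=label) for p in paths]
    if len(sets) == 1:
        return sets[0]
    if len(sets) == 2:
        return replicate_reproducible(sets[0], sets[1])
    raise ValueError("a track takes one file or two replicate files")


def run_landscape(
    tracks: Mapping[str, IntervalSet],
    tss_table: Sequence[TSSRecord],
    de: list[DEResult],
    config: AnalysisConfig | None = None,
) -> LandscapeResult:
    """Core analysis on already-loaded tracks.

    ``tracks`` must hold the six keys atac_a, k4_a, k27_a, atac_b, k4_b,
    k27_b (replicate-reproducible sets if replicates were given).
    """
    config = config or AnalysisConfig()
    changes = tss_accessibility_table(
        de, tracks["atac_a"], tracks["atac_b"], tss_table, config
    )
    calls = call_enhancers(
        tracks["atac_a"], tracks["k4_a"], tracks["k27_a"],
        tracks["atac_b"], tracks["k4_b"], tracks["k27_b"],
        tss_table, config,
    )
    calls = [classify_modality(c, tracks["atac_a"], tracks["k4_a"]) for c in calls]
    calls = attach_de_status(calls, de)
    report = build_report(calls, changes, de)
    return LandscapeResult(de=de, changes=changes, calls=calls, report=report)


def _study_tracks(study: SyntheticStudy) -> dict[str, IntervalSet]:
    p = study.params
    tracks = {}
    for key, track, cond in (
        ("atac_a", "atac", p.cond_a), ("k4_a", "h3k4me1", p.cond_a),
        ("k27_a", "h3k27ac", p.cond_a), ("atac_b", "atac", p.cond_b),
        ("k4_b", "h3k4me1", p.cond_b), ("k27_b", "h3k27ac", p.cond_b),
    ):
        tracks[key] = load_track(
            [study.emitted[f"{track}_{cond}_rep1"], study.emitted[f"{track}_{cond}_rep2"]],
            label=f"{track}_{cond}",
        )
    return tracks


def run_study_landscape(
    study: SyntheticStudy, config: AnalysisConfig | None = None
) -> LandscapeResult:
    """Run the landscape analysis on a simulated study's emitted files."""
    config = config or AnalysisConfig()
    expr = read_expression(study.emitted["expression"])
    tss = read_tss_table(study.emitted["tss"])
    de = differential_expression(expr, study.params.cond_a, study.params.cond_b, config)
    return run_landscape(_study_tracks(study), tss, de, config)


def modality_recovery(
    study: SyntheticStudy, result: LandscapeResult | None = None,
    config: AnalysisConfig | None = None,
) -> float:
    """Fraction of planted enhancers recovered with the correct modality."""
    if result is None:
        result = run_study_landscape(study, config)
    called = {c.region.name: c.modality for c in result.calls}
    hits = sum(
        1 for te in study.truth_enhancers if called.get(te.name) == te.modality
    )
    return hits / len(study.truth_enhancers)


def run_en7_nomination(study: SyntheticStudy, config: AnalysisConfig | None = None):
    """Nominate candidates on a multi-condition accessibility/loop fixture."""
    config = config or AnalysisConfig()
    meta = study.meta
    atac = {
        cond: read_bed(study.emitted[f"atac_{cond}"], label=f"atac_{cond}")
        for cond in meta["conditions"]
    }
    loops = {
        cond: read_bedpe(study.emitted[f"loops_{cond}"], config.hic_resolution, cond)
        for cond in meta["conditions"]
    }
    elements = read_bed(study.emitted["elements"], label="elements")
    tss = read_tss_table(study.emitted["tss"])
    return nominate_candidates(
        meta["gene"], elements, atac, loops,
        required_loop_conditions=meta["required_loop_conditions"],
        forbidden_loop_conditions=meta["forbidden_loop_conditions"],
        min_accessible=meta["min_accessible"],
        tss_table=tss,
        promoter_half_window=config.tss_half_window,
    )


def run_pipeline(
    out_dir: str | Path,
    params: SimulationParams | None = None,
    config: AnalysisConfig | None = None,
) -> Path:
    """Simulate a study and run every stage, writing outputs and a manifest.

    Outputs land in ``out_dir``: the simulated inputs under ``inputs/``,
    then de.tsv, tss_changes.tsv, enhancer_calls.bed, report.txt,
    candidates.tsv (for the first planted loop gene, when loops exist) and
    manifest.json. Identical params/config reproduce byte-identical
    analytic outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = params or SimulationParams()
    config = config or AnalysisConfig()
    timer = StageTimer()

    timer.start("simulate")
    study = simulate_study(params, out_dir / "inputs")
    timer.stop("simulate")

    timer.start("landscape")
    result = run_study_landscape(study, config)
    timer.stop("landscape")

    write_de_table(out_dir / "de.tsv", result.de)
    write_changes_tsv(out_dir / "tss_changes.tsv", result.changes)
    write_calls_bed(out_dir / "enhancer_calls.bed", result.calls)
    write_report(out_dir / "report.txt", result.report)

    if study.truth_loops:
        timer.start("nominate")
        gene = study.truth_loops[0].gene_id
        elements = IntervalSet(
            [te.region for te in study.truth_enhancers], label="planted_enhancers"
        )
        atac_by_cond = {
            params.cond_a: load_track(
                [study.emitted[f"atac_{params.cond_a}_rep1"],
                 study.emitted[f"atac_{params.cond_a}_rep2"]]),
            params.cond_b: load_track(
                [study.emitted[f"atac_{params.cond_b}_rep1"],
                 study.emitted[f"atac_{params.cond_b}_rep2"]]),
        }
        loops_by_cond = {
            cond: read_bedpe(study.emitted[f"loops_{cond}"], config.hic_resolution, cond)
            for cond in (params.cond_a, params.cond_b)
        }
        candidates = nominate_candidates(
            gene, elements, atac_by_cond, loops_by_cond,
            required_loop_conditions=list(params.loop_condition_pattern),
            min_accessible=1,
            tss_table=read_tss_table(study.emitted["tss"]),
            promoter_half_window=config.tss_half_window,
        )
        write_candidates_tsv(out_dir / "candidates.tsv", candidates,
                             [params.cond_a, params.cond_b])
        timer.stop("nominate")

    manifest = RunManifest(config=config, seed=params.seed, timings=timer.timings)
    for role in ("tss", "expression"):
        manifest.add_input(role, study.emitted[role])
    manifest.write(out_dir / "manifest.json")
    log.info("pipeline complete: %s", out_dir)
    return out_dir
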