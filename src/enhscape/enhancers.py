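"""Condition-specific enhancer identification and modality classification.

An induced-state (condition B) enhancer is a region that is
H3K4me1+/H3K27ac+/ATAC+ in B and has *acquired* H3K27ac (no overlapping
H3K27ac peak in the prior state A). The B H3K27ac peak span anchors the
region. Each call is then classified by its prior-state chromatin into one
of four activation modalities from the 2x2 of (ATAC, H3K4me1) status in A:

    (ATAC+, K4me1-)  accessible   open but unprimed before induction
    (ATAC+, K4me1+)  poised       open and primed
    (ATAC-, K4me1-)  unmarked     neither open nor primed
    (ATAC-, K4me1+)  de_novo      primed but closed

Alongside, the TSS-accessibility table intersects differential expression
with the presence of an ATAC peak in the +/-2 kb window around each gene's
TSS in either condition (gained / lost / stable_open / stable_closed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .config import AnalysisConfig
from .de import DEResult
from .intervals import (
    GenomicInterval,
    IntervalSet,
    TSSRecord,
    nearest_tss,
    window_around,
)

log = logging.getLogger(__name__)

__all__ = [
    "MODALITIES",
    "EnhancerCall",
    "TSSAccessibilityChange",
    "LandscapeReport",
    "call_enhancers",
    "classify_modality",
    "attach_de_status",
    "tss_accessibility_table",
    "build_report",
    "write_calls_bed",
    "write_changes_tsv",
]

MODALITIES = ("accessible", "poised", "unmarked", "de_novo")

# (condA ATAC, condA H3K4me1) -> modality
_MODALITY_MAP = {
    (True, False): "accessible",
    (True, True): "poised",
    (False, False): "unmarked",
    (False, True): "de_novo",
}


@dataclass(frozen=True)
class EnhancerCall:
    region: GenomicInterval
    condB_status: tuple[bool, bool, bool]  # (atac, k4me1, k27ac) — always all True
    condA_status: tuple[bool, bool, bool] | None  # k27ac entry always False
    modality: str | None
    nearest_gene: str | None
    tss_distance: int | None
    nearest_gene_de_status: str | None = None


@dataclass(frozen=True)
class TSSAccessibilityChange:
    gene_id: str
    de_status: str
    atac_a: bool
    atac_b: bool

    @property
    def change(self) -> str:
        if not self.atac_a and self.atac_b:
            return "gained"
        if self.atac_a and not self.atac_b:
            return "lost"
        return "stable_open" if self.atac_a else "stable_closed"


def call_enhancers(
    atac_a: IntervalSet,
    k4_a: IntervalSet,
    k27_a: IntervalSet,
    atac_b: IntervalSet,
    k4_b: IntervalSet,
    k27_b: IntervalSet,
    tss_table: Sequence[TSSRecord],
    config: AnalysisConfig | None = None,
) -> list[EnhancerCall]:
    """Candidate condition-B-specific enhancers (modality unset).

    Candidates are condition-B H3K27ac peaks overlapping both a B H3K4me1
    peak and a B ATAC peak, with no overlapping A H3K27ac peak. With
    ``config.distal_filter`` (default on), regions overlapping the
    +/-``distal_min_tss_distance`` window of any TSS are dropped so that
    "enhancer" excludes promoter-proximal regions. ``k4_a`` is accepted here
    only for signature symmetry of the six tracks; prior-state marks are
    consulted by :func:`classify_modality`.
    """
    config = config or AnalysisConfig()
    for track, label in ((atac_b, "ATAC B"), (k4_b, "H3K4me1 B"), (k27_b, "H3K27ac B")):
        if len(track) == 0:
            log.warning("empty %s track: no enhancers can be called", label)
    tss_windows = IntervalSet(
        [
            window_around(rec.tss, config.distal_min_tss_distance, chrom=rec.chrom)
            for rec in tss_table
        ],
        label="tss_windows",
    )
    calls: list[EnhancerCall] = []
    n_proximal = 0
    for peak in k27_b:
        if not (atac_b.overlaps_any(peak) and k4_b.overlaps_any(peak)):
            continue
        if k27_a.overlaps_any(peak):
            continue
        if config.distal_filter and tss_windows.overlaps_any(peak):
            n_proximal += 1
            continue
        gene, dist = (None, None)
        if tss_table:
            try:
                gene, dist = nearest_tss(peak, tss_table)
            except Exception:
                gene, dist = None, None
        calls.append(
            EnhancerCall(
                region=peak,
                condB_status=(True, True, True),
                condA_status=None,
                modality=None,
                nearest_gene=gene,
                tss_distance=dist,
            )
        )
    log.info(
        "enhancer calling: %d candidate region(s); %d dropped by distal filter",
        len(calls), n_proximal,
    )
    return calls


def classify_modality(
    call: EnhancerCall, atac_a: IntervalSet, k4_a: IntervalSet
) -> EnhancerCall:
    """Assign the prior-state activation modality to one call.

    The class decision uses peak presence/absence only; prior-state signal
    tiers ("low"/"lowest" H3K4me1) are descriptive and never decide the
    class.
    """
    atac = atac_a.overlaps_any(call.region)
    k4 = k4_a.overlaps_any(call.region)
    return replace(
        call,
        condA_status=(atac, k4, False),
        modality=_MODALITY_MAP[(atac, k4)],
    )


def attach_de_status(
    calls: Sequence[EnhancerCall], de: Sequence[DEResult]
) -> list[EnhancerCall]:
    """Fill ``nearest_gene_de_status`` from a DE result list."""
    status = {r.gene_id: r.status for r in de}
    return [
        replace(c, nearest_gene_de_status=status.get(c.nearest_gene))
        for c in calls
    ]


def tss_accessibility_table(
    de: Sequence[DEResult],
    atac_a: IntervalSet,
    atac_b: IntervalSet,
    tss_table: Sequence[TSSRecord],
    config: AnalysisConfig | None = None,
) -> list[TSSAccessibilityChange]:
    """Per-gene TSS accessibility status in both conditions.

    A gene's TSS is "accessible" in a condition when >=1 ATAC peak overlaps
    the +/-``tss_half_window`` window around the TSS. Genes absent from the
    TSS table are skipped with a logged count.
    """
    config = config or AnalysisConfig()
    tss_by_gene = {rec.gene_id: rec for rec in tss_table}
    out: list[TSSAccessibilityChange] = []
    skipped = 0
    for r in de:
        rec = tss_by_gene.get(r.gene_id)
        if rec is None:
            skipped += 1
            continue
        win = window_around(rec.tss, config.tss_half_window, chrom=rec.chrom)
        out.append(
            TSSAccessibilityChange(
                gene_id=r.gene_id,
                de_status=r.status,
                atac_a=atac_a.overlaps_any(win),
                atac_b=atac_b.overlaps_any(win),
            )
        )
    if skipped:
        log.info("tss_accessibility_table: %d gene(s) absent from the TSS table", skipped)
    return out


@dataclass(frozen=True)
class LandscapeReport:
    """Headline counts and percentages of the regulatory landscape."""

    n_enhancers: int
    modality_counts: dict[str, int]
    modality_percent: dict[str, float | None]
    n_up: int
    n_up_gained: int
    pct_up_with_gain: float | None
    n_down: int
    n_down_lost: int
    pct_down_with_loss: float | None
    n_enhancers_near_up: int
    pct_enhancers_near_upregulated: float | None
    upregulated_gene_counts_per_modality: dict[str, int]
    pct_upregulated_per_modality: dict[str, float | None]


def build_report(
    calls: Sequence[EnhancerCall],
    changes: Sequence[TSSAccessibilityChange],
    de: Sequence[DEResult],
    decimals: int = 0,
) -> LandscapeReport:
    """Aggregate calls, TSS changes and DE into the landscape report.

    Percentages are rounded half-up to ``decimals`` (default 0); raw counts
    and denominators are always carried alongside so rounding never hides
    information. Zero denominators yield None ("NA"), never an error.
    The per-modality association percentages count distinct upregulated
    nearest genes per modality against all distinct upregulated nearest
    genes of called enhancers.
    """
    from .report import report_percent

    counts = {m: 0 for m in MODALITIES}
    for c in calls:
        if c.modality is None:
            raise ValueError("build_report requires classified calls")
        counts[c.modality] += 1
    n = len(calls)
    pct = {m: report_percent(counts[m], n, decimals) for m in MODALITIES}

    up = [c for c in changes if c.de_status == "up"]
    down = [c for c in changes if c.de_status == "down"]
    n_up_gained = sum(1 for c in up if c.change == "gained")
    n_down_lost = sum(1 for c in down if c.change == "lost")

    near_up = [c for c in calls if c.nearest_gene_de_status == "up"]
    genes_per_modality: dict[str, set[str]] = {m: set() for m in MODALITIES}
    for c in near_up:
        genes_per_modality[c.modality].add(c.nearest_gene)
    all_up_genes = set().union(*genes_per_modality.values()) if near_up else set()

    return LandscapeReport(
        n_enhancers=n,
        modality_counts=counts,
        modality_percent=pct,
        n_up=len(up),
        n_up_gained=n_up_gained,
        pct_up_with_gain=report_percent(n_up_gained, len(up), decimals),
        n_down=len(down),
        n_down_lost=n_down_lost,
        pct_down_with_loss=report_percent(n_down_lost, len(down), decimals),
        n_enhancers_near_up=len(near_up),
        pct_enhancers_near_upregulated=report_percent(len(near_up), n, decimals),
        upregulated_gene_counts_per_modality={
            m: len(genes_per_modality[m]) for m in MODALITIES
        },
        pct_upregulated_per_modality={
            m: report_percent(len(genes_per_modality[m]), len(all_up_genes), decimals)
            for m in MODALITIES
        },
    )


def _na(x) -> str:
    return "NA" if x is None else f"{x:g}"


def write_report(path, rep: LandscapeReport) -> None:
    """Human-readable landscape report (counts + percentages)."""
    lines = [f"enhancers called\t{rep.n_enhancers}"]
    for m in MODALITIES:
        lines.append(
            f"modality {m}\t{rep.modality_counts[m]}/{rep.n_enhancers}"
            f"\t{_na(rep.modality_percent[m])}%"
        )
    lines.append(
        f"upregulated genes gaining TSS accessibility\t{rep.n_up_gained}/{rep.n_up}"
        f"\t{_na(rep.pct_up_with_gain)}%"
    )
    lines.append(
        f"downregulated genes losing TSS accessibility\t{rep.n_down_lost}/{rep.n_down}"
        f"\t{_na(rep.pct_down_with_loss)}%"
    )
    lines.append(
        f"enhancers with upregulated nearest gene\t{rep.n_enhancers_near_up}/{rep.n_enhancers}"
        f"\t{_na(rep.pct_enhancers_near_upregulated)}%"
    )
    for m in MODALITIES:
        lines.append(
            f"upregulated genes associated with {m} enhancers"
            f"\t{rep.upregulated_gene_counts_per_modality[m]}"
            f"\t{_na(rep.pct_upregulated_per_modality[m])}%"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_calls_bed(path, calls: Sequence[EnhancerCall]) -> None:
    """Enhancer calls as BED6+ (modality, condA flags, nearest gene, distance, DE)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom\tstart\tend\tname\tscore\tstrand\tmodality"
            "\tcondA_atac\tcondA_k4me1\tnearest_gene\ttss_distance\tnearest_gene_de_status\n"
        )
        for i, c in enumerate(calls):
            a = c.condA_status or (False, False, False)
            fh.write(
                f"{c.region.chrom}\t{c.region.start}\t{c.region.end}"
                f"\t{c.region.name or f'enh_{i}'}\t.\t.\t{c.modality or '.'}"
                f"\t{int(a[0])}\t{int(a[1])}\t{c.nearest_gene or '.'}"
                f"\t{c.tss_distance if c.tss_distance is not None else '.'}"
                f"\t{c.nearest_gene_de_status or '.'}\n"
            )


def write_changes_tsv(path, changes: Sequence[TSSAccessibilityChange]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tde_status\tatac_a\tatac_b\tchange\n")
        for c in changes:
            fh.write(
                f"{c.gene_id}\t{c.de_status}\t{int(c.atac_a)}\t{int(c.atac_b)}\t{c.change}\n"
            )
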