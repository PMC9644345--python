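"""Hi-C loop integration and candidate-enhancer nomination.

Significant interactions (binned BEDPE, typically 10 kb anchors) are
annotated with per-anchor open-chromatin status from the condition-matched
ATAC peak set and with the genes whose promoter window overlaps each
anchor. Candidate enhancers for a gene are then nominated across
conditions by the pattern that surfaced the Pax7 En7 element: accessible
in at least ``min_accessible`` conditions, looped to the gene's promoter
in every required condition, and unlooped in every forbidden condition
("loop absent" means no qualifying interaction row for that condition —
absence of evidence, by design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .intervals import GenomicInterval, IntervalSet, TSSRecord, window_around
from .io import Interaction
from .errors import GeneNotFound, UnknownCondition

log = logging.getLogger(__name__)

__all__ = ["AnchoredInteraction", "CandidateEnhancer", "annotate_interactions",
           "nominate_candidates", "write_candidates_tsv"]


@dataclass(frozen=True)
class AnchoredInteraction:
    interaction: Interaction
    anchor1_open: bool
    anchor2_open: bool
    anchor1_genes: tuple[str, ...]
    anchor2_genes: tuple[str, ...]


@dataclass(frozen=True)
class CandidateEnhancer:
    element: GenomicInterval
    target_gene: str
    accessible_conditions: frozenset[str]
    looped_conditions: frozenset[str]
    score: int  # 1-based rank
    supported: bool


def _promoter_windows(
    tss_table: Sequence[TSSRecord], half_window: int
) -> list[tuple[TSSRecord, GenomicInterval]]:
    return [
        (rec, window_around(rec.tss, half_window, chrom=rec.chrom))
        for rec in tss_table
    ]


def annotate_interactions(
    interactions: Sequence[Interaction],
    atac_by_condition: Mapping[str, IntervalSet],
    tss_table: Sequence[TSSRecord],
    promoter_half_window: int = 2000,
) -> list[AnchoredInteraction]:
    """Open-chromatin and promoter annotation per anchor.

    Open flags derive solely from the ATAC set of the interaction's own
    condition. Annotation is invariant to anchor order (anchors are
    canonicalized first).
    """
    windows = _promoter_windows(tss_table, promoter_half_window)
    out = []
    for inter in interactions:
        if inter.condition not in atac_by_condition:
            raise UnknownCondition(
                f"interaction condition {inter.condition!r} has no ATAC track"
            )
        inter = inter.canonical()
        atac = atac_by_condition[inter.condition]
        genes = []
        for anchor in (inter.anchor1, inter.anchor2):
            hits = tuple(
                sorted(rec.gene_id for rec, win in windows
                       if win.chrom == anchor.chrom
                       and win.start < anchor.end and anchor.start < win.end)
            )
            genes.append(hits)
        out.append(
            AnchoredInteraction(
                interaction=inter,
                anchor1_open=atac.overlaps_any(inter.anchor1),
                anchor2_open=atac.overlaps_any(inter.anchor2),
                anchor1_genes=genes[0],
                anchor2_genes=genes[1],
            )
        )
    return out


def nominate_candidates(
    gene_id: str,
    elements: IntervalSet,
    atac_by_condition: Mapping[str, IntervalSet],
    interactions_by_condition: Mapping[str, Sequence[Interaction]],
    required_loop_conditions: Sequence[str],
    forbidden_loop_conditions: Sequence[str] = (),
    min_accessible: int = 1,
    tss_table: Sequence[TSSRecord] = (),
    promoter_half_window: int = 2000,
) -> list[CandidateEnhancer]:
    """Rank candidate enhancers of ``gene_id`` across conditions.

    For each element: its accessible conditions are those whose ATAC set
    overlaps it; its looped conditions are those with a cis interaction one
    anchor bin of which overlaps the element while the other anchor bin
    overlaps the gene's promoter window. An element is supported when it is
    accessible in >= ``min_accessible`` conditions, looped in every required
    condition, and looped in no forbidden one. Ranking: more accessible
    conditions first, then more required loops, then genomic position —
    deterministic and stable under input row permutation.
    """
    rec = next((r for r in tss_table if r.gene_id == gene_id), None)
    if rec is None:
        raise GeneNotFound(f"gene {gene_id!r} absent from the TSS table")
    promoter = window_around(rec.tss, promoter_half_window, chrom=rec.chrom)
    required = frozenset(required_loop_conditions)
    forbidden = frozenset(forbidden_loop_conditions)

    rows = []
    for element in elements:
        accessible = frozenset(
            cond for cond, atac in atac_by_condition.items()
            if atac.overlaps_any(element)
        )
        looped = set()
        for cond, inters in interactions_by_condition.items():
            for inter in inters:
                inter = inter.canonical()
                if not inter.is_cis:
                    continue  # enhancer-promoter pairs are cis
                a1, a2 = inter.anchor1, inter.anchor2
                def _hits(x: GenomicInterval, y: GenomicInterval) -> bool:
                    return x.chrom == y.chrom and x.start < y.end and y.start < x.end
                if (_hits(a1, element) and _hits(a2, promoter)) or (
                    _hits(a2, element) and _hits(a1, promoter)
                ):
                    looped.add(cond)
                    break
        looped = frozenset(looped)
        supported = (
            len(accessible) >= min_accessible
            and required <= looped
            and not (forbidden & looped)
        )
        rows.append((element, accessible, looped, supported))

    rows.sort(
        key=lambda r: (
            -len(r[1]),
            -len(r[2] & required),
            r[0].chrom,
            r[0].start,
            r[0].end,
        )
    )
    out = [
        CandidateEnhancer(
            element=el,
            target_gene=gene_id,
            accessible_conditions=acc,
            looped_conditions=lo,
            score=i + 1,
            supported=sup,
        )
        for i, (el, acc, lo, sup) in enumerate(rows)
    ]
    log.info(
        "nominate %s: %d element(s), %d supported",
        gene_id, len(out), sum(c.supported for c in out),
    )
    return out


def write_candidates_tsv(path, candidates: Sequence[CandidateEnhancer],
                         conditions: Sequence[str]) -> None:
    with open(path, "w") as fh:
        cols = [f"atac_{c}" for c in conditions] + [f"loop_{c}" for c in conditions]
        fh.write("chrom\tstart\tend\tname\ttarget_gene\t" + "\t".join(cols)
                 + "\tsupported\trank\n")
        for c in candidates:
            flags = [str(int(cond in c.accessible_conditions)) for cond in conditions]
            flags += [str(int(cond in c.looped_conditions)) for cond in conditions]
            fh.write(
                f"{c.element.chrom}\t{c.element.start}\t{c.element.end}"
                f"\t{c.element.name or '.'}\t{c.target_gene}\t" + "\t".join(flags)
                + f"\t{int(c.supported)}\t{c.score}\n"
            )
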