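"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive: nested all-pairs scans with no
indexing, re-deriving results straight from interval lists. The oracles
share no code path with the implementation they check.
"""

from __future__ import annotations


def brute_overlaps(a, b) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def brute_presence(query, subject) -> list[bool]:
    return [any(brute_overlaps(q, s) for s in subject) for q in query]


def brute_nearest(region, tss_table):
    """Nearest TSS by midpoint distance; ties to smaller gene_id; reported
    distance 0 when the TSS sits inside the region, else signed by strand."""
    mid = (region.start + region.end) // 2
    on_chrom = [r for r in tss_table if r.chrom == region.chrom]
    assert on_chrom
    best = min(on_chrom, key=lambda r: (abs(mid - r.tss), r.gene_id))
    if region.start <= best.tss < region.end:
        return best.gene_id, 0
    d = mid - best.tss
    return best.gene_id, d if best.strand == "+" else -d


def brute_rp10m_counts(regions, tags) -> list[int]:
    return [sum(1 for t in tags if brute_overlaps(r, t)) for r in regions]


def brute_call_and_classify(atac_a, k4_a, k27_a, atac_b, k4_b, k27_b,
                            tss_table, distal_bp=2000, distal_filter=True):
    """All-pairs re-derivation of enhancer calls and modalities.

    Returns {region name or coords: modality} for every qualifying
    condition-B H3K27ac peak.
    """
    out = {}
    for peak in k27_b:
        if not any(brute_overlaps(peak, p) for p in atac_b):
            continue
        if not any(brute_overlaps(peak, p) for p in k4_b):
            continue
        if any(brute_overlaps(peak, p) for p in k27_a):
            continue
        if distal_filter and any(
            peak.chrom == r.chrom
            and peak.start < r.tss + distal_bp
            and max(0, r.tss - distal_bp) < peak.end
            for r in tss_table
        ):
            continue
        atac = any(brute_overlaps(peak, p) for p in atac_a)
        k4 = any(brute_overlaps(peak, p) for p in k4_a)
        modality = {
            (True, False): "accessible",
            (True, True): "poised",
            (False, False): "unmarked",
            (False, True): "de_novo",
        }[(atac, k4)]
        key = peak.name or f"{peak.chrom}:{peak.start}-{peak.end}"
        out[key] = modality
    return out


def brute_tss_changes(de, atac_a, atac_b, tss_table, half_window=2000):
    """{gene: (atac_a, atac_b)} over DE genes present in the TSS table."""
    tss_by_gene = {r.gene_id: r for r in tss_table}
    out = {}
    for res in de:
        rec = tss_by_gene.get(res.gene_id)
        if rec is None:
            continue
        lo, hi = max(0, rec.tss - half_window), rec.tss + half_window
        def hit(track):
            return any(
                p.chrom == rec.chrom and p.start < hi and lo < p.end for p in track
            )
        out[res.gene_id] = (hit(atac_a), hit(atac_b))
    return out


def brute_annotate(interactions, atac_by_condition, tss_table, half_window=2000):
    """Triple intersection per anchor: (open1, open2, genes1, genes2)."""
    rows = []
    for inter in interactions:
        atac = atac_by_condition[inter.condition]
        anchors = sorted(
            [inter.anchor1, inter.anchor2], key=lambda a: (a.chrom, a.start)
        )
        row = []
        for anchor in anchors:
            row.append(any(brute_overlaps(anchor, p) for p in atac))
        for anchor in anchors:
            genes = sorted(
                r.gene_id for r in tss_table
                if r.chrom == anchor.chrom
                and max(0, r.tss - half_window) < anchor.end
                and anchor.start < r.tss + half_window
            )
            row.append(tuple(genes))
        rows.append(tuple(row))
    return rows
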