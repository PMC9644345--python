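"""Two-condition multi-omic fixture generator with planted ground truth.

The generator emulates the structure of a two-state cell transition
experiment: a replicate RPKM expression matrix with planted fold changes
and multiplicative log-normal replicate noise; per-condition, per-replicate
ATAC / H3K4me1 / H3K27ac peak tracks in which every planted condition-B
enhancer carries all three marks in B, has no H3K27ac in A, and shows the
prior-state (ATAC, H3K4me1) pattern of its planted modality class; tag
libraries consistent with peak presence; and a BEDPE loop table with
planted enhancer-promoter contacts present or absent per condition.

Genes are laid out on a jittered grid of non-overlapping blocks across a
handful of toy chromosomes, so nearest-TSS assignment of each planted
enhancer resolves to its own target gene by construction. Noise
(``peak_fdr_noise``) is a per-enhancer corruption probability: with that
probability one uniformly chosen mark/condition slot of the enhancer flips
(a true peak dropped or a spurious peak emitted), so planted-class
recovery degrades as roughly 1 - noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleLayout
from .intervals import GenomicInterval, TSSRecord
from .io import (
    ExpressionTable,
    Interaction,
    write_bed,
    write_bedpe,
    write_expression,
    write_tss_table,
)

__all__ = [
    "SimulationParams",
    "SyntheticStudy",
    "simulate_study",
    "make_en7_fixture",
    "largest_remainder",
    "CLASS_NAMES",
]

CLASS_NAMES = ("accessible", "poised", "unmarked", "de_novo")

# prior-state (ATAC, H3K4me1) presence per modality class
_CLASS_PRIOR = {
    "accessible": (True, False),
    "poised": (True, True),
    "unmarked": (False, False),
    "de_novo": (False, True),
}

# Observed class mix of the 1,482-region landscape: 597/386/379/120.
PAPER_CLASS_MIX = (597 / 1482, 386 / 1482, 379 / 1482, 120 / 1482)

# Block sizes of the jittered layout grid (bp). Enhancer-bearing genes get a
# wide block so the enhancer lands >10 kb from the promoter (distinct Hi-C
# bins); plain genes only need non-overlapping +/-2 kb TSS windows.
_BLOCK_ENH = 30_000
_BLOCK_PLAIN = 6_000
_TSS_OFFSET = 2_000
_ENH_OFFSET = 14_000


def largest_remainder(n: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``n`` items by largest-remainder rounding.

    Quotas ``n * w`` are rounded at 1e-9 to keep float dust out of the
    remainders; leftover items go to the largest remainders, ties favoring
    the smaller class, then the earlier index. Counts always sum to ``n``.
    """
    quotas = [round(n * w, 9) for w in weights]
    floors = [int(math.floor(q)) for q in quotas]
    deficit = n - sum(floors)
    if deficit < 0:
        raise ValueError("weights sum above 1; cannot apportion")
    order = sorted(
        range(len(weights)),
        key=lambda i: (-(quotas[i] - floors[i]), floors[i], i),
    )
    for i in order[:deficit]:
        floors[i] += 1
    return floors


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_genes: int = 500
    n_enhancers: int = 100
    class_proportions: tuple[float, float, float, float] = PAPER_CLASS_MIX
    frac_up: float = 0.15
    frac_down: float = 0.10
    frac_low: float = 0.05            # genes planted below the 1 RPKM floor
    frac_enh_target_up: float = 0.25  # enhancers whose nearest gene is upregulated
    frac_up_gain: float = 1385 / 2022  # up genes gaining TSS accessibility
    frac_down_loss: float = 479 / 1288  # down genes losing TSS accessibility
    planted_log2fc: float = 1.0
    replicate_cv: float = 0.1
    n_replicates: int = 4
    peak_fdr_noise: float = 0.0
    n_loops: int = 20
    loop_condition_pattern: tuple[str, ...] = ("instructed",)
    cond_a: str = "naive"
    cond_b: str = "instructed"
    chrom_sizes: Mapping[str, int] | None = None  # None -> auto-sized toy genome
    tags_per_peak: int = 5
    hic_resolution: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 0.01:
            raise ValueError("class_proportions must sum to 1")
        if any(not (0 <= p <= 1) for p in self.class_proportions):
            raise ValueError("class_proportions must lie in [0, 1]")
        for name in ("frac_up", "frac_down", "frac_low", "frac_enh_target_up",
                     "frac_up_gain", "frac_down_loss", "peak_fdr_noise"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_up + self.frac_down + self.frac_low > 1:
            raise ValueError("frac_up + frac_down + frac_low must be <= 1")
        if self.n_enhancers > self.n_genes:
            raise ValueError("n_enhancers must be <= n_genes")
        if self.n_loops > self.n_enhancers:
            raise ValueError("n_loops must be <= n_enhancers")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


@dataclass(frozen=True)
class TruthGene:
    gene_id: str
    tss: TSSRecord
    status: str           # up / down / ns / low
    accessibility: str    # gained / lost / stable_open / stable_closed
    mean_a: float
    mean_b: float


@dataclass(frozen=True)
class TruthEnhancer:
    name: str
    region: GenomicInterval  # condition-B H3K27ac span (pre-noise)
    modality: str
    target_gene: str
    corrupted: bool          # a noise flip touched one of its mark slots


@dataclass(frozen=True)
class TruthLoop:
    enhancer: str
    gene_id: str
    anchor_enh: GenomicInterval
    anchor_prom: GenomicInterval
    conditions: tuple[str, ...]


@dataclass
class SyntheticStudy:
    """Planted truth plus the emitted input files of one synthetic run."""

    params: SimulationParams | None
    out_dir: Path
    truth_de: dict[str, TruthGene]
    truth_enhancers: list[TruthEnhancer]
    truth_loops: list[TruthLoop]
    emitted: dict[str, Path]
    meta: dict = field(default_factory=dict)


def _place_genes(params: SimulationParams, rng: np.random.Generator):
    """Assign each gene a (chrom, block_start, block_size) on the toy genome."""
    sizes = [
        _BLOCK_ENH if i < params.n_enhancers else _BLOCK_PLAIN
        for i in range(params.n_genes)
    ]
    if params.chrom_sizes is None:
        total = sum(sizes)
        per = total // 3 + _BLOCK_ENH
        chrom_sizes = {"chr1": per, "chr2": per, "chr3": per}
    else:
        chrom_sizes = dict(params.chrom_sizes)
    offsets = {c: 0 for c in chrom_sizes}
    placements = []
    for size in sizes:
        for chrom, limit in chrom_sizes.items():
            if offsets[chrom] + size <= limit:
                placements.append((chrom, offsets[chrom], size))
                offsets[chrom] += size
                break
        else:
            raise InfeasibleLayout(
                f"toy genome of {sum(chrom_sizes.values())} bp cannot host "
                f"{params.n_genes} gene blocks ({sum(sizes)} bp needed)"
            )
    return placements


def _assign_statuses(params: SimulationParams, rng: np.random.Generator) -> list[str]:
    n, n_enh = params.n_genes, params.n_enhancers
    n_up = round(params.frac_up * n)
    n_down = round(params.frac_down * n)
    n_low = round(params.frac_low * n)
    n_up_enh = min(round(params.frac_enh_target_up * n_enh), n_up, n_enh)
    if n_up - n_up_enh > n - n_enh:
        raise InfeasibleLayout("not enough non-enhancer genes for the planted up set")
    status = ["ns"] * n
    enh_idx = np.arange(n_enh)
    plain_idx = np.arange(n_enh, n)
    for i in rng.choice(enh_idx, size=n_up_enh, replace=False):
        status[i] = "up"
    for i in rng.choice(plain_idx, size=n_up - n_up_enh, replace=False):
        status[i] = "up"
    free = np.array([i for i in range(n) if status[i] == "ns"])
    for i in rng.choice(free, size=n_down, replace=False):
        status[i] = "down"
    low_pool = np.array(
        [i for i in range(n_enh, n) if status[i] == "ns"]
    )
    if len(low_pool) < n_low:
        raise InfeasibleLayout("not enough plain ns genes for the planted low set")
    for i in rng.choice(low_pool, size=n_low, replace=False):
        status[i] = "low"
    return status


def _assign_accessibility(
    status: list[str], params: SimulationParams, rng: np.random.Generator
) -> list[str]:
    acc = [""] * len(status)
    up_idx = [i for i, s in enumerate(status) if s == "up"]
    down_idx = [i for i, s in enumerate(status) if s == "down"]
    n_gain = round(params.frac_up_gain * len(up_idx))
    n_loss = round(params.frac_down_loss * len(down_idx))
    gain = set(rng.choice(up_idx, size=n_gain, replace=False)) if up_idx else set()
    loss = set(rng.choice(down_idx, size=n_loss, replace=False)) if down_idx else set()
    for i, s in enumerate(status):
        if s == "up":
            acc[i] = "gained" if i in gain else "stable_open"
        elif s == "down":
            acc[i] = "lost" if i in loss else "stable_open"
        else:
            acc[i] = "stable_open" if rng.random() < 0.6 else "stable_closed"
    return acc


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=shape)


def simulate_study(params: SimulationParams, out_dir: str | Path) -> SyntheticStudy:
    """Generate and write one synthetic two-condition study.

    Emits a TSS table; per-condition, per-replicate peak BEDs for
    ATAC/H3K4me1/H3K27ac; tag BEDs (unless ``tags_per_peak`` is 0); the
    replicate RPKM matrix; per-condition BEDPE loop tables; and returns the
    planted-truth record. Re-running with identical params is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    n, n_enh = params.n_genes, params.n_enhancers

    placements = _place_genes(params, rng)
    tss_jit = rng.integers(0, 401, size=n)
    enh_jit = rng.integers(0, 401, size=n)
    strands = rng.choice(["+", "-"], size=n)
    tss_records = []
    enh_centers = []
    for i, (chrom, off, size) in enumerate(placements):
        tss = off + _TSS_OFFSET + int(tss_jit[i])
        tss_records.append(TSSRecord(f"gene_{i:05d}", chrom, tss, str(strands[i])))
        enh_centers.append(tss + _ENH_OFFSET + int(enh_jit[i]) if i < n_enh else None)

    # planted enhancer classes
    counts = largest_remainder(n_enh, params.class_proportions)
    class_ids = np.repeat(np.arange(4), counts)
    rng.shuffle(class_ids)

    status = _assign_statuses(params, rng)
    accessibility = _assign_accessibility(status, params, rng)

    # expression matrix
    base = np.exp(rng.normal(math.log(20.0), 1.0, size=n))
    base = np.clip(base, 2.0, None)
    low_base = 0.05 + 0.45 * rng.random(size=n)
    mean_a = np.where([s == "low" for s in status], low_base, base)
    shift = np.array(
        [2.0 ** params.planted_log2fc if s == "up"
         else 2.0 ** -params.planted_log2fc if s == "down" else 1.0
         for s in status]
    )
    mean_b = mean_a * shift
    reps = params.n_replicates
    noise = _lognormal_noise(rng, params.replicate_cv, (n, 2 * reps))
    values = np.concatenate(
        [mean_a[:, None] * noise[:, :reps], mean_b[:, None] * noise[:, reps:]], axis=1
    )
    columns = [f"{params.cond_a}_{r + 1}" for r in range(reps)] + [
        f"{params.cond_b}_{r + 1}" for r in range(reps)
    ]
    expr = ExpressionTable([r.gene_id for r in tss_records], columns, values)

    # mark-presence slots per enhancer: ((A atac, A k4, A k27), (B atac, B k4, B k27))
    slot_flip = rng.random(size=n_enh) < params.peak_fdr_noise
    flip_slot = rng.integers(0, 6, size=n_enh)
    truth_enh: list[TruthEnhancer] = []
    presence = []
    for e in range(n_enh):
        modality = CLASS_NAMES[class_ids[e]]
        atac_a, k4_a = _CLASS_PRIOR[modality]
        slots = [atac_a, k4_a, False, True, True, True]
        corrupted = bool(slot_flip[e])
        if corrupted:
            j = int(flip_slot[e])
            slots[j] = not slots[j]
        presence.append(slots)
        chrom = placements[e][0]
        c = enh_centers[e]
        truth_enh.append(
            TruthEnhancer(
                name=f"enh_{e:05d}",
                region=GenomicInterval(chrom, c - 250, c + 250, name=f"enh_{e:05d}"),
                modality=modality,
                target_gene=f"gene_{e:05d}",
                corrupted=corrupted,
            )
        )

    # assemble peak lists per (track, condition)
    half = {"atac": 200, "h3k4me1": 225, "h3k27ac": 250}
    peaks: dict[tuple[str, str], list[GenomicInterval]] = {
        (t, c): []
        for t in ("atac", "h3k4me1", "h3k27ac")
        for c in (params.cond_a, params.cond_b)
    }
    for i, rec in enumerate(tss_records):  # promoter ATAC peaks
        acc = accessibility[i]
        in_a = acc in ("stable_open", "lost")
        in_b = acc in ("stable_open", "gained")
        peak = GenomicInterval(rec.chrom, rec.tss - 300, rec.tss + 300, name=f"tss_{rec.gene_id}")
        if in_a:
            peaks[("atac", params.cond_a)].append(peak)
        if in_b:
            peaks[("atac", params.cond_b)].append(peak)
    for e, te in enumerate(truth_enh):
        c = enh_centers[e]
        chrom = te.region.chrom
        slots = presence[e]
        for k, track in enumerate(("atac", "h3k4me1", "h3k27ac")):
            h = half[track]
            iv = GenomicInterval(chrom, c - h, c + h, name=te.name)
            if slots[k]:
                peaks[(track, params.cond_a)].append(iv)
            if slots[3 + k]:
                peaks[(track, params.cond_b)].append(iv)

    emitted: dict[str, Path] = {}
    tss_path = out_dir / "tss.bed"
    write_tss_table(tss_path, tss_records)
    emitted["tss"] = tss_path
    expr_path = out_dir / "expression.tsv"
    write_expression(expr_path, expr)
    emitted["expression"] = expr_path

    for (track, cond), plist in peaks.items():
        plist = sorted(plist, key=GenomicInterval.sort_key)
        jitters = rng.integers(-20, 21, size=len(plist))
        for rep in (1, 2):
            if rep == 1:
                out = plist
            else:
                out = [
                    GenomicInterval(p.chrom, max(0, p.start + int(j)), p.end + int(j), p.name)
                    for p, j in zip(plist, jitters)
                ]
            path = out_dir / f"{track}_{cond}_rep{rep}.bed"
            write_bed(path, out)
            emitted[f"{track}_{cond}_rep{rep}"] = path
        if params.tags_per_peak > 0:
            tags = []
            for p in plist:
                pos = rng.integers(p.start, max(p.start + 1, p.end - 50),
                                   size=params.tags_per_peak)
                tags.extend(
                    GenomicInterval(p.chrom, int(q), int(q) + 50) for q in sorted(pos)
                )
            path = out_dir / f"{track}_{cond}_tags.bed"
            write_bed(path, sorted(tags, key=GenomicInterval.sort_key))
            emitted[f"{track}_{cond}_tags"] = path

    # planted loops between promoter and enhancer bins
    res = params.hic_resolution
    pattern = params.loop_condition_pattern
    per_loop = (
        list(pattern)
        if pattern and isinstance(pattern[0], (tuple, list))
        else [tuple(pattern)] * params.n_loops
    )
    truth_loops: list[TruthLoop] = []
    loops_by_cond: dict[str, list[Interaction]] = {
        params.cond_a: [], params.cond_b: []
    }
    scores = 5 + 45 * rng.random(size=params.n_loops)
    for j in range(params.n_loops):
        te = truth_enh[j]
        rec = tss_records[j]
        b_enh = (enh_centers[j] // res) * res
        b_prom = (rec.tss // res) * res
        anchor_enh = GenomicInterval(te.region.chrom, b_enh, b_enh + res)
        anchor_prom = GenomicInterval(rec.chrom, b_prom, b_prom + res)
        conds = tuple(per_loop[j])
        truth_loops.append(TruthLoop(te.name, rec.gene_id, anchor_enh, anchor_prom, conds))
        for cond in conds:
            if cond not in loops_by_cond:
                raise ValueError(f"loop pattern condition {cond!r} is not a study condition")
            loops_by_cond[cond].append(
                Interaction(anchor_prom, anchor_enh, condition=cond,
                            score=float(round(scores[j], 3))).canonical()
            )
    for cond, inters in loops_by_cond.items():
        path = out_dir / f"loops_{cond}.bedpe"
        write_bedpe(path, inters)
        emitted[f"loops_{cond}"] = path

    truth_de = {
        rec.gene_id: TruthGene(
            gene_id=rec.gene_id,
            tss=rec,
            status="low" if status[i] == "low" else status[i],
            accessibility=accessibility[i],
            mean_a=float(mean_a[i]),
            mean_b=float(mean_b[i]),
        )
        for i, rec in enumerate(tss_records)
    }
    return SyntheticStudy(
        params=params,
        out_dir=out_dir,
        truth_de=truth_de,
        truth_enhancers=truth_enh,
        truth_loops=truth_loops,
        emitted=emitted,
        meta={"conditions": [params.cond_a, params.cond_b]},
    )


def make_en7_fixture(out_dir: str | Path) -> SyntheticStudy:
    """Five-condition accessibility/loop fixture with one true candidate.

    Mirrors the discovery setting of the Pax7 En7 intronic enhancer: the
    true element is accessible in the four myogenic-lineage conditions and
    loops to the promoter in aPSM and HIFLR but not in pluripotent ESCs.
    Two decoys (-25 kb and -3.5 kb analogs) are accessible but never
    looped; one decoy loops but is never accessible.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conditions = ("ESC", "aPSM", "HIFLR", "MuSC", "somite")
    open_conds = ("aPSM", "HIFLR", "MuSC", "somite")
    chrom, res = "chr4", 10_000
    tss = 139_758_500
    pax7 = TSSRecord("Pax7", chrom, tss, "+")
    elements = {
        "En7": GenomicInterval(chrom, 139_771_035, 139_771_985, name="En7"),
        "minus25kb": GenomicInterval(chrom, 139_733_500, 139_734_100, name="minus25kb"),
        "minus3.5kb": GenomicInterval(chrom, 139_754_800, 139_755_400, name="minus3.5kb"),
        "looped_closed": GenomicInterval(chrom, 139_790_500, 139_791_100, name="looped_closed"),
    }
    promoter_peak = GenomicInterval(chrom, tss - 300, tss + 300, name="tss_Pax7")
    far_peak = GenomicInterval(chrom, 139_900_000, 139_900_600, name="bg")

    emitted: dict[str, Path] = {}
    tss_path = out_dir / "tss.bed"
    write_tss_table(tss_path, [pax7])
    emitted["tss"] = tss_path
    el_path = out_dir / "elements.bed"
    write_bed(el_path, sorted(elements.values(), key=GenomicInterval.sort_key))
    emitted["elements"] = el_path

    for cond in conditions:
        if cond in open_conds:
            atac = [elements["En7"], elements["minus25kb"], elements["minus3.5kb"],
                    promoter_peak]
        else:
            atac = [far_peak]
        path = out_dir / f"atac_{cond}.bed"
        write_bed(path, sorted(atac, key=GenomicInterval.sort_key))
        emitted[f"atac_{cond}"] = path

    def _bin(pos: int) -> GenomicInterval:
        b = (pos // res) * res
        return GenomicInterval(chrom, b, b + res)

    prom_bin = _bin(tss)
    en7_bin = _bin(elements["En7"].start)
    closed_bin = _bin(elements["looped_closed"].start)
    loops_by_cond: dict[str, list[Interaction]] = {c: [] for c in conditions}
    for cond in ("aPSM", "HIFLR"):
        loops_by_cond[cond] = [
            Interaction(prom_bin, en7_bin, condition=cond, score=20.0).canonical(),
            Interaction(prom_bin, closed_bin, condition=cond, score=12.0).canonical(),
        ]
    # an unrelated distal contact keeps the pluripotent table non-empty
    loops_by_cond["ESC"] = [
        Interaction(_bin(139_900_000), _bin(139_930_000), condition="ESC", score=8.0)
    ]
    for cond, inters in loops_by_cond.items():
        path = out_dir / f"loops_{cond}.bedpe"
        write_bedpe(path, inters)
        emitted[f"loops_{cond}"] = path

    truth = TruthEnhancer(
        name="En7", region=elements["En7"], modality="poised", target_gene="Pax7",
        corrupted=False,
    )
    loops = [
        TruthLoop("En7", "Pax7", en7_bin, prom_bin, ("aPSM", "HIFLR")),
        TruthLoop("looped_closed", "Pax7", closed_bin, prom_bin, ("aPSM", "HIFLR")),
    ]
    return SyntheticStudy(
        params=None,
        out_dir=out_dir,
        truth_de={},
        truth_enhancers=[truth],
        truth_loops=loops,
        emitted=emitted,
        meta={
            "conditions": list(conditions),
            "gene": "Pax7",
            "required_loop_conditions": ("aPSM", "HIFLR"),
            "forbidden_loop_conditions": ("ESC",),
            "min_accessible": 4,
        },
    )
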