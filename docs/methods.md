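# Methods

`enhscape` integrates bulk multi-omic evidence across a two-state cell
transition — a prior condition A (e.g. naive ESCs) and an induced
condition B (e.g. Bmp4-instructed ESCs) — to characterise the regulatory
landscape of the transition and to nominate candidate enhancers from
chromatin-loop evidence. This note records the models, conventions,
parameter choices and their rationale.

## Coordinate model

All intervals are 0-based, half-open (BED convention). Two spans overlap
iff they share at least one base; adjacency (`a.end == b.start`) is not an
overlap. "Peak presence" over a region means ≥1 bp overlap with ≥1 peak —
no reciprocal-fraction requirement, since presence/absence is the only
decision the analysis needs and 1 bp is the permissive default. Interval
sets are indexed per chromosome with an interval tree; duplicate spans
(common in tag libraries) remain distinct members.

Replicate peak tracks are reduced with the both-replicates rule: only
regions called in both replicates enter downstream analysis. The first
replicate supplies the coordinates of the surviving regions; a span merge
would manufacture coordinates found in neither call set.

### Nearest-TSS assignment

A region is assigned to the gene whose TSS minimises the distance to the
region midpoint, ties broken by lexicographically smaller `gene_id` so the
assignment is reproducible. The reported distance is 0 when the TSS falls
inside the region; otherwise it is the midpoint distance, signed positive
when the midpoint lies downstream of the TSS in the gene's orientation.
Strand affects only the sign, never eligibility — enhancers act
strand-agnostically. (Midpoint-vs-edge distance is a genuine convention
choice; tools differ, and the midpoint rule is the one documented and
tested here.)

## Signal quantification

Peak/region intensities are normalised as tags per 10 million reads of the
original library (RP10M): `count x 1e7 / library_size`. Profile matrices
split a symmetric window (±2 kb around a TSS, ±10 kb around a peak center,
by default) into equal bins; each tag is assigned to the bin containing
its midpoint, which makes row sums additive with whole-window counts
(exactly so for point tags such as insertion or cut sites; approximately
for wide fragments straddling a bin edge).

## Differential expression

Inputs are replicate RPKM values; the package never quantifies from reads.
The decision rule is: a gene is **up** (resp. **down**) when the
raw-RPKM condition-mean fold change B/A is ≥ 1.5 (resp. ≤ 1/1.5), the
adjusted p-value is < 0.05, and the better-expressed condition reaches
1 RPKM. Genes below the floor are never tested (`low_expression`).

The test engine is a Welch two-sample t-test on log2(RPKM + 1) —
the two-group reduction of a one-way ANOVA on the log scale — with
Benjamini–Hochberg adjustment across the tested genes. Both choices are
deliberate defaults rather than claims about any particular upstream
toolchain: the thresholds are the scientific content of the filter, the
engine is pluggable (an external raw-p column can be supplied, after which
only the threshold logic applies). Zero-variance-in-both-groups genes have
an undefined statistic; they fall back to p = 1 with a logged warning.
Fold change uses no pseudocount: a zero-baseline gene expressed in B gets
an infinite ratio, which correctly passes the ratio threshold; genes near
zero in both conditions are screened out by the expression floor first.

Swapping the condition labels exactly inverts fold changes and leaves the
Welch p unchanged, so up/down statuses exchange exactly — this is tested
as an invariant.

## Enhancer calling and modality classification

A condition-B-specific enhancer is a B H3K27ac peak that (i) overlaps a B
H3K4me1 peak and a B ATAC peak (H3K4me1+/H3K27ac+/ATAC+ in the induced
state), and (ii) overlaps **no** A H3K27ac peak — the active mark must be
acquired during the transition. The B H3K27ac span anchors the region
coordinates, matching the convention of centering downstream analyses on
the acquired-signal regions. A distal filter (on by default, configurable)
drops regions overlapping the ±2 kb window of any TSS, so "enhancer"
excludes promoter-proximal elements.

Each call is classified by its prior-state chromatin into the 2×2 of
(ATAC, H3K4me1) presence in condition A:

| condition A state | modality |
|---|---|
| ATAC+, H3K4me1− | accessible |
| ATAC+, H3K4me1+ | poised |
| ATAC−, H3K4me1− | unmarked |
| ATAC−, H3K4me1+ | de novo |

Presence/absence of peak calls — not a signal threshold — decides the
class; prior-state H3K4me1 RP10M can be attached as a descriptive tier but
never enters the decision. The four classes partition the call set by
construction.

The TSS-accessibility table intersects the DE statuses with ATAC presence
in the ±2 kb TSS window per condition, yielding gained / lost /
stable_open / stable_closed per gene. The landscape report aggregates:
class counts and percentages, the fraction of up genes gaining and down
genes losing TSS accessibility, the fraction of enhancers whose nearest
gene is upregulated, and the distribution of distinct upregulated nearest
genes across modalities. Percentages are rounded half-up (never banker's)
at a configurable precision, always printed next to their raw counts, and
a zero denominator reports NA rather than raising.

## Loop integration and candidate nomination

Significant Hi-C interactions are consumed as a BEDPE table — the package
performs no significance testing. Anchors are snapped to the resolution
grid (10 kb by default, matching extraction at 10 kb resolution with a
25 kb window) and ordered canonically, so annotation is invariant to
anchor order in the input. Each anchor is flagged open iff the
condition-matched ATAC set overlaps it, and annotated with the genes whose
±2 kb promoter window overlaps the anchor bin.

Candidate enhancers of a gene are nominated across an arbitrary set of
conditions by the pattern that identifies a functional element like the
Pax7 En7 intronic enhancer:

- **accessible** in at least `min_accessible` conditions (ATAC overlap);
- **looped** to the gene's promoter in every *required* condition — a cis
  interaction with one anchor bin overlapping the element and the other
  overlapping the promoter window;
- **unlooped** in every *forbidden* condition. "Loop absent" means no
  qualifying interaction row for that condition; the criterion is absence
  of evidence by design, which is exactly the discriminating observation
  ("contact not detected in the pluripotent state").

Element-to-anchor matching is ≥1 bp against the anchor bin: the data are
bin-resolution, so finer matching has no basis in the input.
Trans-chromosomal interactions are carried through annotation but never
qualify for support. Ranking is by (number of accessible conditions desc,
required loops hit desc, genomic position asc) — deterministic and stable
under input row permutation.

## Synthetic data generator

The generator plants a complete truth record and emits exactly the
formats the readers consume, so every stage is testable end to end without
external data.

**Layout.** Genes occupy non-overlapping blocks on three toy chromosomes
(auto-sized to the requested counts; ~10 Mb at the 500-gene default):
30 kb blocks for enhancer-bearing genes, 6 kb otherwise. The TSS sits
~2 kb into the block and the enhancer ~14 kb downstream of its target
TSS (small uniform jitter on both), which guarantees: the enhancer's
nearest TSS is its own target; it clears the ±2 kb distal filter; and the
enhancer and promoter fall in different 10 kb bins so planted loops have
two distinct anchors. A genome that cannot host the requested counts
raises an explicit layout error rather than silently overlapping elements.

**Classes and apportionment.** Planted class counts are the
largest-remainder apportionment of `class_proportions` (default: the
observed mix 597:386:379:120, i.e. proportions that sum exactly to 1).
Quotas are rounded at 1e-9 before decomposition so float dust cannot
reorder remainders, and remainder ties go to the smaller class. Counts
always sum exactly to `n_enhancers`.

**Expression.** Baseline RPKM is log-normal (median ~20, clipped ≥2 so
expressed genes stay clear of the 1 RPKM floor); planted up/down genes
shift the condition-B mean by ±`planted_log2fc`. Replicate noise is
multiplicative log-normal with coefficient of variation `replicate_cv`,
mean-preserving — the standard dispersion surrogate for RNA-seq on the
log scale. Four replicates per condition is the default: a noncentral-t
power calculation at the default effect size (log2FC 1, CV 0.1) gives
>99% per-gene power at BH-scale thresholds, whereas three replicates sit
near the edge and two are underpowered. A planted `frac_low` of genes is
given sub-floor expression to exercise the `low_expression` path.

**Accessibility and association.** Fractions of up genes planted as
"gained" and of down genes as "lost" default to the observed 1385/2022
and 479/1288; `frac_enh_target_up` (default 0.25) fixes the fraction of
enhancers whose target gene is planted up. Remaining genes are
stable-open or stable-closed.

**Peaks, noise, tags, loops.** Every planted enhancer emits B-condition
ATAC/H3K4me1/H3K27ac peaks and the prior-state peaks of its class; both
replicates carry each peak (the second with a ±20 bp coordinate jitter, so
the both-replicates rule is genuinely exercised). `peak_fdr_noise` is a
per-enhancer corruption probability: with that probability, one uniformly
chosen of the six mark/condition slots flips — a true peak dropped or a
spurious one emitted at the element. Any flip corrupts the call or its
class, so recovery degrades as ≈ 1 − noise and is monotone in it; this
per-element definition is the generator's declared assumption (the assays'
real error structure is not modelled). Tag files emit a fixed number of
tags uniformly inside each peak. Loops connect promoter and enhancer bins
of the first `n_loops` planted enhancers, present per condition according
to `loop_condition_pattern`.

Generation is fully driven by one seeded RNG; identical parameters give
byte-identical files.

**The five-condition loop fixture** (`make_en7_fixture`) reconstructs the
discovery geometry of the Pax7 En7 element on chr4: the true intronic
candidate (accessible in aPSM/HIFLR/MuSC/somite, looped to the promoter in
aPSM and HIFLR, unlooped in ESCs), two accessible-but-unlooped upstream
decoys (−25 kb and −3.5 kb analogs), and one looped-but-inaccessible
decoy. The −3.5 kb decoy deliberately falls inside the promoter's own
10 kb bin, exercising the requirement that the *other* anchor of a
qualifying loop must reach the promoter.

### What the generator does and does not emulate

It reproduces the combinatorial structure the pipeline reasons about —
mark co-occurrence patterns, replicate concordance, planted effect sizes,
bin-resolution contacts — with clean geometry and independent noise. It
does not model read-level artifacts, fragment-size effects, peak-width or
signal-strength distributions, correlated replicate failures, copy-number
or mappability biases, or distance-dependent Hi-C background. Passing
tests therefore demonstrate the correctness of the integration logic
under its stated definitions, not the pipeline's robustness to every
failure mode of real libraries.

## Problem sizes used in the checks

The printed-ratio fixture plants 1,482 enhancers among 4,000 genes
(2,022 up / 1,288 down) with log2FC 2 and CV 0.05 — a strong, clean
two-state response under which the planted counts pass the DE filter
without attrition, so the report's integer percentages are exact. Oracle
equivalence runs 20 studies of 60 genes / 30 enhancers at noise 0.1
against all-pairs re-derivations; recovery properties use 10 seeds of
80/60 at noise 0, 0.05 and 0.2; DE properties use 2,000 genes at log2FC 1,
CV 0.1. The whole suite and the acceptance script each complete in well
under a minute.

## Known limitations

- The DE engine is a two-group Welch/BH pipeline; multi-group designs and
  shrinkage estimators are out of scope (the p column is pluggable).
- Nearest-TSS uses midpoint distance; tools using edge distance can
  assign boundary cases differently.
- Candidate support treats loop absence as evidence of absence, inheriting
  the sensitivity of the upstream interaction caller.
- Enhancer-gene association is nearest-TSS only; no activity-by-contact
  or correlation-based linking.
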