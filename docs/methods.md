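# Methods

This note records the models, conventions and design decisions behind
loopscape, in the order the pipeline runs.

## Coordinate model

All internal coordinates are 0-based, half-open (BED convention); readers
for 1-based dialects (refFlat-style gene tables) convert at the boundary.
Overlap between `[a, b)` and `[c, d)` is `max(0, min(b, d) − max(a, c))`,
so abutting intervals never overlap. Deterministic orderings break ties by
(chromosome lexicographic, start, end, name). A loop's anchors are ordered
by midpoint and its size is the distance between anchor midpoints, which
stays well defined for unequal anchor widths. BEDPE records joining two
chromosomes are skipped with a counted warning rather than raised: all
loop analyses here are intra-chromosomal, and a hard failure on a stray
trans record would be hostile to real loop lists. HiCCUPS-style header
lines (second column non-numeric, first line only) are skipped silently;
chromosome names are kept verbatim with no `chr` aliasing. The overlap
engine is backed by interval trees and is checked in the test suite
against a quadratic all-against-all oracle.

## Loop–TAD classification

Anchor∈TAD is tested by **anchor midpoint** containment in
`[tad.start, tad.end)`, not by any-overlap: anchors are fixed-width bins
that can straddle TAD boundaries, and the midpoint rule yields an
unambiguous partition (an any-overlap mode is available via
`containment_mode`). Nested TADs are handled with an existence quantifier
over all TADs — a loop inside both a child TAD and its parent is *intra* —
so no unique TAD assignment is needed and the result is invariant to TAD
order and duplicates. Categories: intra (some TAD contains both
midpoints), inter (each midpoint in at least one TAD, no TAD containing
both), one-anchor, not-in-TAD. The long-loop census counts sizes strictly
greater than the threshold (default 3 Mb, 3 000 000 bp).

Size distributions are compared with the two-sided Mann–Whitney U test
(normal approximation with tie and continuity correction); the
per-chromosome variant applies Benjamini–Hochberg across chromosomes,
leaving chromosomes empty in either condition out of the adjustment
family. The method is the standard choice for skewed size distributions;
no distributional form is assumed.

## Compartments

A bin is compartment A iff its eigenvector value is positive and B iff
negative — the sign exactly, no thresholding; a value of exactly 0 leaves
the bin unassigned and excluded from medians, since the sign rule is
undefined there. Genes attach to compartments through a strand-aware
promoter window, 2 kb upstream / 500 bp downstream of the TSS (TSS =
txStart on +, txEnd on −; unstranded models are rejected), clipped at the
chromosome ends. When a promoter intersects several bins the
largest-overlap bin is kept, ties going to the lower start coordinate. All
transcript isoforms are called individually; the per-gene consensus is the
majority label, ties resolved by the longest transcript (then smallest
transcript id) — a deterministic reduction is required even though
gene-level summaries are what get reported.

Expression is summarised as `log2(FPKM + 1)`. The pseudocount of 1 keeps
unexpressed genes finite and is the dominant convention; because of it the
recovered A−B median difference on synthetic data sits slightly below the
planted difference on the raw log2 scale (the B-side medians are inflated
more by the +1), which is why the recovery tolerance is 0.3 rather than a
few hundredths.

Differential-compartment tables (dcHiC-style: chrom, start, end,
per-cell-type PC columns, `padj`) are consumed, not recomputed; filtering
keeps `padj < alpha` strictly.

## CTCF integration

**Peak sharing** uses merged-interval event semantics: peaks are merged
within each set (≥ 1 bp overlap merges; abutting intervals deliberately do
not), the cross-set union is merged the same way, and each union event is
labeled by which sets cover it. The shared percentage is fixed as
100·shared/union (one decimal). One-to-one matched counts obey the same
formula through `sharing_percent_from_counts(n1, n2, shared)` =
100·shared/(n1+n2−shared); both semantics agree on the generator, whose
planted peaks are well separated. The overlap criterion is ≥ 1 bp; no
reciprocal-fraction requirement is imposed.

**Anchor binding**: an anchor is CTCF-bound when at least one peak
overlaps the anchor interval extended by `slack` bp per side (default 0).
The 0/1/2 class proportions over a loop set always sum to 1.

**Meta-profiles**: the reference point is the peak summit when the
narrowPeak summit column is non-negative, else the interval midpoint.
Offset bins tile `[−flank, +flank)` (flank must be divisible by the bin
width; defaults 5 kb / 100 bp). Within a peak each bin is the
overlap-length-weighted mean of the track records it touches; across
peaks, the per-bin mean runs over peaks with at least one covered record —
uncovered bases contribute nothing, not zero, matching bedGraph coverage
conventions (densify the track to force zero-fill).

**Cross-analysis**: genes ranked by the chosen expression column
(descending, ties by gene id), top-N (default 100) taken, the longest
transcript per gene chosen (tie: smallest transcript id), length-weighted
mean CTCF/Pol II signal computed over the transcript interval, and
non-coding genes dropped afterwards when `coding_only` — so the output row
count is top-N minus non-coding minus genes lacking a model (censused).

## Annotation and enrichment

Anchor annotation precedence is promoter > exon > intron > intergenic,
with the gene id taken from the first matching gene in (chromosome, start)
order. The promoter window for contact analyses is 2 kb upstream / 100 bp
downstream of the TSS by default; a narrower 1 kb-upstream variant is a
parameter (`--upstream 1000`) since both conventions are in circulation.
Over-representation is the upper-tail hypergeometric probability
P(X ≥ k) with population = all genes in the supplied gene-model file
(overridable), term sizes intersected with that universe, empty terms
skipped rather than reported at p = 1, and Benjamini–Hochberg adjustment
across the tested terms.

## Synthetic data generator

The generator's defaults define the study conditions the tests exercise:

* **Genome**: two chromosomes, 6 Mb + 4 Mb. Small enough that the full
  suite and the acceptance battery run in seconds, large enough for ~50
  TADs and 1 Mb compartment blocks per cell type.
* **TADs**: log-normal sizes, ln-median 200 kb, log-sd 0.5 (sizes clipped
  to 60 kb–1.5 Mb), tiled left-to-right with 20–60 kb gaps; a TAD longer
  than 150 kb receives one strictly nested child with probability 0.3
  (nesting depth ≤ 2 — enough to exercise the nested-TAD ambiguity
  without unbounded recursion).
* **Loops**: 60/25/20/15 intra/inter/one-anchor/not-in-TAD per cell type,
  10 kb fixed-width anchors (mirroring 10 kb-binned loop calls), placed so
  each category's definition holds by construction under the midpoint
  rule; anchor midpoints snap to the CpG grid so peak centers align with
  methylation records.
* **CTCF peaks**: 400 bp wide, summit at center; at each loop anchor with
  probability 0.6, plus background peaks planted with explicit sharing
  membership (30 epithelium-only, 50 fiber-only, 20 shared by default),
  kept ≥ max(3 peak widths, 2 dip half-widths) apart so sharing recovery
  is exact and dips do not interfere at profile centers.
* **Compartments**: 1 Mb blocks alternating +2/−2 eigenvector, emitted as
  10 kb bins. Genes (300; 5–20 kb; 2–4 exons; 15% non-coding) are placed
  in pre-computed non-overlapping slots wholly inside blocks of their
  planted label, so promoter windows never straddle a boundary unless
  `n_boundary_genes` asks for straddlers (TSS 500 bp inside a block edge,
  putting the larger promoter half in the neighbouring block — those are
  the only genes the assignment may mislabel).
* **Expression**: FPKM = 2^x with x ~ Normal(5, 1) in A and Normal(3, 1)
  in B per cell type, so the pipeline's log2 transform recovers the
  planted values; a few "crystallin-like" genes get x ~ Normal(12, 1) in
  the fiber cell type (Normal(9, 1) in epithelium) to give the
  cross-analysis an unambiguous top cohort.
* **Methylation**: per-CpG records (2 bp) on a regular 50 bp grid at
  baseline 0.8, with linear dips of depth 0.7 and half-width 500 bp
  centered on each CTCF peak; overlapping dips take the deeper value.
  Because centers sit on the grid, a 50 bp-binned meta-profile recovers
  the dip depth exactly at the center bin.
* **Coverage**: Pol II (and per-cell CTCF coverage, emitted so the
  cross-analysis is exercisable end-to-end) is constant over each gene
  body at 0.01 × FPKM — gene-body signal proportional to expression by
  construction.

A fixed seed makes every emitted file byte-identical across runs. What the
generator does **not** emulate: read-level noise, contact-matrix
structure, peak-width/signal distributions of real ChIP-seq, isoform
complexity (one transcript per gene is emitted; multi-isoform handling is
tested on hand-built models), CpG-density variation, or biological
correlation between compartment switching and differential expression
across cell types. Passing recovery tests therefore demonstrates the
correctness of the interval algebra, classification rules and reductions —
not robustness to the noise of real data.

## Pipeline

A YAML config names inputs per cell type; stages auto-enable when their
inputs are present and can be toggled. All stages are deterministic, so
identical config and inputs reproduce byte-identical tables; every table
carries a provenance comment (version, config hash, seed) with no
timestamps. A stage failure is isolated: partial outputs are retained, the
report marks the stage failed, and the CLI exits non-zero. Warnings
(skipped inter-chromosomal records, genes without expression or models)
are always counted in the report, never silent.

## Problem sizes

Defaults throughout were chosen so the complete test suite runs in well
under a minute and the acceptance battery in seconds: recovery checks use
a scaled-down 3 Mb + 2 Mb two-chromosome genome with the same per-feature
parameters as the defaults, and the expression-recovery condition uses a
32 Mb genome carrying 500 genes per compartment, the size at which a
median difference of 2 is recovered within 0.3.
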