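"""A/B compartment labeling and gene-to-compartment assignment.

Compartment membership follows the sign of the per-bin eigenvector value:
positive values are compartment A (active), negative values compartment B
(inactive); a value of exactly zero leaves the bin unassigned. Genes are
attached to compartments through their promoters (strand-aware window,
default 2 kb upstream / 500 bp downstream of the TSS): when a promoter
spans several bins the bin with the largest overlap wins, ties going to the
lower start coordinate. All transcript isoforms are assigned individually
and reduced to a per-gene consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    ParseError,
    SignalTrack,
    overlap_length,
)

__all__ = [
    "CompartmentBin",
    "GeneCompartmentCall",
    "ExpressionByCompartment",
    "promoter_region",
    "bins_from_track",
    "read_pc_bedgraph",
    "assign_gene_compartment",
    "assign_genes",
    "gene_consensus",
    "expression_by_compartment",
    "read_differential_table",
    "filter_significant",
]

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


@dataclass(frozen=True)
class CompartmentBin:
    """A fixed-width genomic bin carrying an eigenvector (PC) value."""

    region: GenomicInterval
    pc_value: float
    padj: float | None = None

    @property
    def label(self) -> str:
        if self.pc_value > 0:
            return "A"
        if self.pc_value < 0:
            return "B"
        return "unassigned"


@dataclass(frozen=True)
class GeneCompartmentCall:
    gene_id: str
    transcript_id: str
    promoter: GenomicInterval
    chosen_bin: CompartmentBin
    label: str
    overlap_bp: int


def promoter_region(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom_size: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    Plus strand: ``[TSS - upstream, TSS + downstream)``; minus strand:
    ``[TSS - downstream, TSS + upstream)``. Raises for unstranded genes,
    whose TSS is undefined.
    """
    tss = gene.tss  # raises ValueError when unstranded
    if gene.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    start = max(0, start)
    if chrom_size is not None:
        end = min(end, chrom_size)
    return GenomicInterval(gene.chrom, start, end, gene.strand, gene.gene_id)


def bins_from_track(track: SignalTrack) -> list[CompartmentBin]:
    """Compartment bins from an eigenvector signal track (already sorted and
    non-overlapping by the track invariant)."""
    return [
        CompartmentBin(region=iv, pc_value=value)
        for iv, value in track.iter_records()
    ]


def read_pc_bedgraph(path) -> list[CompartmentBin]:
    from .intervals import read_intervals

    return bins_from_track(read_intervals(path, format="bedGraph"))


def _check_bins(bins: Sequence[CompartmentBin]) -> None:
    by_chrom: dict[str, list[CompartmentBin]] = {}
    for b in bins:
        by_chrom.setdefault(b.region.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        bs = sorted(bs, key=lambda b: b.region.start)
        for prev, cur in zip(bs, bs[1:]):
            if cur.region.start < prev.region.end:
                raise ValueError(f"overlapping compartment bins on {chrom}")


def assign_gene_compartment(
    gene: GeneModel,
    bins: Sequence[CompartmentBin],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    _validate: bool = True,
) -> GeneCompartmentCall | None:
    """Largest-overlap compartment call for one transcript's promoter.

    Returns None when the promoter intersects no bin. Ties on overlap are
    broken by the lower bin start coordinate.
    """
    if _validate:
        _check_bins(bins)
    prom = promoter_region(gene, upstream, downstream)
    best: tuple[int, int] | None = None  # (-overlap, start) for min()
    best_bin: CompartmentBin | None = None
    for b in bins:
        ov = overlap_length(prom, b.region)
        if ov <= 0:
            continue
        key = (-ov, b.region.start)
        if best is None or key < best:
            best = key
            best_bin = b
    if best_bin is None:
        return None
    return GeneCompartmentCall(
        gene_id=gene.gene_id,
        transcript_id=gene.transcript_id,
        promoter=prom,
        chosen_bin=best_bin,
        label=best_bin.label,
        overlap_bp=-best[0],
    )


def assign_genes(
    genes: Iterable[GeneModel],
    bins: Sequence[CompartmentBin],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> list[GeneCompartmentCall]:
    """Per-isoform compartment calls for every stranded transcript model."""
    _check_bins(bins)
    calls = []
    for gene in genes:
        call = assign_gene_compartment(
            gene, bins, upstream, downstream, _validate=False
        )
        if call is not None:
            calls.append(call)
    return calls


def gene_consensus(
    calls: Sequence[GeneCompartmentCall],
    genes: Iterable[GeneModel] | None = None,
) -> dict[str, str]:
    """Reduce per-isoform calls to one label per gene.

    Majority label across isoforms; a tie goes to the label of the longest
    transcript (then lexicographically smallest transcript_id). Unassigned
    isoform calls (pc exactly 0) do not vote unless they are all there is.
    """
    lengths: dict[str, int] = {}
    if genes is not None:
        lengths = {g.transcript_id: g.length for g in genes}
    by_gene: dict[str, list[GeneCompartmentCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene_id, []).append(c)
    out: dict[str, str] = {}
    for gene_id, cs in by_gene.items():
        voting = [c for c in cs if c.label in ("A", "B")] or cs
        tally: dict[str, int] = {}
        for c in voting:
            tally[c.label] = tally.get(c.label, 0) + 1
        top = max(tally.values())
        winners = sorted(lbl for lbl, n in tally.items() if n == top)
        if len(winners) == 1:
            out[gene_id] = winners[0]
        else:
            ranked = sorted(
                voting,
                key=lambda c: (-lengths.get(c.transcript_id, 0), c.transcript_id),
            )
            out[gene_id] = ranked[0].label
    return out


@dataclass
class ExpressionByCompartment:
    """log2(FPKM + 1) distributions and medians per compartment label."""

    medians: dict[str, float]
    distributions: dict[str, np.ndarray]
    n_missing_expression: int

    def to_frame(self) -> pd.DataFrame:
        labels = sorted(self.distributions)
        return pd.DataFrame(
            {
                "label": labels,
                "n_genes": [len(self.distributions[l]) for l in labels],
                "median_log2_fpkm": [self.medians[l] for l in labels],
            }
        )


def expression_by_compartment(
    gene_labels: Mapping[str, str],
    expression: Mapping[str, float] | pd.Series,
    pseudocount: float = 1.0,
) -> ExpressionByCompartment:
    """Per-compartment expression summary on the log2(FPKM + pseudocount)
    scale. Genes with no expression value are excluded and counted; a label
    with no genes reports a NaN median."""
    if isinstance(expression, pd.Series):
        expression = expression.to_dict()
    values: dict[str, list[float]] = {"A": [], "B": []}
    n_missing = 0
    for gene_id, label in gene_labels.items():
        if label not in values:
            values[label] = []
        fpkm = expression.get(gene_id)
        if fpkm is None or (isinstance(fpkm, float) and math.isnan(fpkm)):
            n_missing += 1
            continue
        values[label].append(math.log2(fpkm + pseudocount))
    dists = {lbl: np.array(v, dtype=float) for lbl, v in values.items()}
    medians = {
        lbl: (float(np.median(v)) if len(v) else math.nan)
        for lbl, v in dists.items()
    }
    return ExpressionByCompartment(medians, dists, n_missing)


def read_differential_table(path) -> pd.DataFrame:
    """Read a differential-compartment table (dcHiC-style output).

    Requires columns chrom, start, end and padj; per-cell-type PC columns
    are carried through untouched.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    return df


def filter_significant(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bins with adjusted significance below alpha (strict)."""
    return table[table["padj"] < alpha].reset_index(drop=True)
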