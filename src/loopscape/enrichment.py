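"""Loop-anchor annotation, promoter-contact gene sets and hypergeometric
over-representation analysis (ORA).

Anchors are annotated against gene models with a fixed precedence
promoter > exon > intron > intergenic, the promoter being a strand-aware
window around the TSS (default 2 kb upstream / 100 bp downstream for
contact analyses). Over-representation uses the upper-tail hypergeometric
test with Benjamini–Hochberg adjustment across tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .intervals import GeneModel, GenomicInterval, Loop, overlap_length
from .compartments import promoter_region

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorAnnotation",
    "EnrichmentResult",
    "CONTACT_PROMOTER_UPSTREAM",
    "CONTACT_PROMOTER_DOWNSTREAM",
    "annotate_anchor",
    "annotate_anchors",
    "promoter_contact_genes",
    "contact_sharing",
    "enrich",
]

# Promoter window for contact analyses; the narrower in-text variant
# (1 kb upstream) is available by passing upstream=1000.
CONTACT_PROMOTER_UPSTREAM = 2000
CONTACT_PROMOTER_DOWNSTREAM = 100

ANNOTATION_PRECEDENCE = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class AnchorAnnotation:
    value: str  # promoter | exon | intron | intergenic
    gene_id: str | None = None


def _sorted_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    return sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.transcript_id))


def annotate_anchor(
    anchor: GenomicInterval,
    genes: Sequence[GeneModel],
    upstream: int = CONTACT_PROMOTER_UPSTREAM,
    downstream: int = CONTACT_PROMOTER_DOWNSTREAM,
    _presorted: bool = False,
) -> AnchorAnnotation:
    """Annotate one anchor with precedence promoter > exon > intron >
    intergenic; gene_id is the first matching gene in (chrom, start) order."""
    ordered = genes if _presorted else _sorted_genes(genes)
    exon_gene = intron_gene = None
    for g in ordered:
        if g.chrom != anchor.chrom:
            continue
        if g.strand in "+-":
            prom = promoter_region(g, upstream, downstream)
            if overlap_length(anchor, prom) > 0:
                return AnchorAnnotation("promoter", g.gene_id)
        if exon_gene is None:
            for ex_start, ex_end in g.exons:
                if max(0, min(anchor.end, ex_end) - max(anchor.start, ex_start)) > 0:
                    exon_gene = g.gene_id
                    break
        if exon_gene is None and intron_gene is None:
            if overlap_length(anchor, g.body) > 0:
                intron_gene = g.gene_id
    if exon_gene is not None:
        return AnchorAnnotation("exon", exon_gene)
    if intron_gene is not None:
        return AnchorAnnotation("intron", intron_gene)
    return AnchorAnnotation("intergenic")


def annotate_anchors(
    loops: Iterable[Loop],
    genes: Sequence[GeneModel],
    upstream: int = CONTACT_PROMOTER_UPSTREAM,
    downstream: int = CONTACT_PROMOTER_DOWNSTREAM,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Annotate every loop anchor; returns the per-anchor table and the
    proportion of anchors in each category (summing to 1)."""
    ordered = _sorted_genes(genes)
    rows = []
    for i, loop in enumerate(loops):
        for which, anchor in (("anchor1", loop.anchor1), ("anchor2", loop.anchor2)):
            ann = annotate_anchor(
                anchor, ordered, upstream, downstream, _presorted=True
            )
            rows.append(
                {
                    "loop_index": i,
                    "anchor": which,
                    "chrom": anchor.chrom,
                    "start": anchor.start,
                    "end": anchor.end,
                    "annotation": ann.value,
                    "gene_id": ann.gene_id or "",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "loop_index", "anchor", "chrom", "start", "end", "annotation", "gene_id",
        ],
    )
    n = len(df)
    props = {
        cat: (float((df["annotation"] == cat).sum()) / n if n else 0.0)
        for cat in ANNOTATION_PRECEDENCE
    }
    return df, props


def promoter_contact_genes(
    loops: Iterable[Loop],
    genes: Sequence[GeneModel],
    upstream: int = CONTACT_PROMOTER_UPSTREAM,
    downstream: int = CONTACT_PROMOTER_DOWNSTREAM,
) -> set[str]:
    """Genes with at least one loop anchor overlapping their promoter window."""
    out: set[str] = set()
    stranded = [g for g in genes if g.strand in "+-"]
    proms = [(g.gene_id, promoter_region(g, upstream, downstream)) for g in stranded]
    for loop in loops:
        for anchor in (loop.anchor1, loop.anchor2):
            for gene_id, prom in proms:
                if gene_id not in out and overlap_length(anchor, prom) > 0:
                    out.add(gene_id)
    return out


def contact_sharing(
    sets: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], int]:
    """Exact 7-region Venn counts over three named gene sets.

    Keys are sorted tuples of the set names containing each gene; values
    sum to the size of the union.
    """
    names = sorted(sets)
    if len(names) != 3:
        raise ValueError("exactly three named gene sets are required")
    members = {name: set(sets[name]) for name in names}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, 4):
        for combo in combinations(names, r):
            counts[combo] = 0
    for gene in set().union(*members.values()):
        combo = tuple(name for name in names if gene in members[name])
        counts[combo] += 1
    return counts


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # query ∩ term
    K: int  # term size within universe
    n: int  # query size
    N: int  # universe size
    p: float  # hypergeometric upper tail P(X >= k)
    q: float  # BH-adjusted


def enrich(
    query: Iterable[str],
    gmt: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a gene set against GMT terms.

    Query genes outside the universe are dropped with a warning; terms are
    intersected with the universe and skipped when empty. Results are
    sorted by p ascending (ties by term_id).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    dropped = query - universe
    if dropped:
        logger.warning(
            "%d query genes outside the universe dropped", len(dropped)
        )
    query &= universe
    N, n = len(universe), len(query)
    rows = []
    for term_id in sorted(gmt):
        term = set(gmt[term_id]) & universe
        K = len(term)
        if K == 0:
            continue
        k = len(term & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, p))
    if not rows:
        return []
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term_id, k, K, n, N, min(1.0, p), float(q))
        for (term_id, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
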