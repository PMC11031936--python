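"""Loop/TAD architecture statistics and the four-way loop-TAD classification.

A loop is placed relative to a TAD set by where its two anchor midpoints
fall: both inside one TAD (intra-TAD), each inside a TAD but never the same
one (inter-TAD), exactly one inside a TAD, or neither. TADs may be nested;
an existence quantifier over all TADs is used, so a loop sitting inside both
a child TAD and its parent is intra-TAD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .intervals import Loop, TAD

__all__ = [
    "LoopTadCategory",
    "ArchitectureSummary",
    "SizeComparison",
    "classify_loop",
    "classify_all",
    "summarize",
    "compare_sizes",
    "compare_sizes_per_chromosome",
    "DEFAULT_LONG_LOOP_THRESHOLD",
]

DEFAULT_LONG_LOOP_THRESHOLD = 3_000_000  # bp; "long-range" loop census cutoff


class LoopTadCategory(enum.Enum):
    INTRA = "intra"
    INTER = "inter"
    ONE_ANCHOR = "one_anchor"
    NOT_IN_TAD = "not_in_tad"


def _contains(tad: TAD, pos: float, anchor=None, mode: str = "midpoint") -> bool:
    if mode == "midpoint":
        return tad.region.start <= pos < tad.region.end
    # any-overlap alternative: the anchor interval itself touches the TAD
    return (
        min(tad.region.end, anchor.end) - max(tad.region.start, anchor.start) > 0
    )


def classify_loop(
    loop: Loop, tads: Sequence[TAD], mode: str = "midpoint"
) -> LoopTadCategory:
    """Assign a loop to one of the four loop-TAD arrangement categories.

    ``mode='midpoint'`` (default) tests anchor-midpoint containment in
    ``[tad.start, tad.end)``; ``mode='overlap'`` tests any anchor/TAD
    overlap. The result is invariant to TAD order and duplicates.
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError(f"unknown containment mode {mode!r}")
    m1, m2 = loop.anchor1.midpoint, loop.anchor2.midpoint
    in1 = in2 = both = False
    for tad in tads:
        if tad.chrom != loop.chrom:
            continue
        c1 = _contains(tad, m1, loop.anchor1, mode)
        c2 = _contains(tad, m2, loop.anchor2, mode)
        in1 = in1 or c1
        in2 = in2 or c2
        both = both or (c1 and c2)
    if both:
        return LoopTadCategory.INTRA
    if in1 and in2:
        return LoopTadCategory.INTER
    if in1 or in2:
        return LoopTadCategory.ONE_ANCHOR
    return LoopTadCategory.NOT_IN_TAD


def classify_all(
    loops: Iterable[Loop], tads: Sequence[TAD], mode: str = "midpoint"
) -> dict[LoopTadCategory, int]:
    """Category counts over a loop set; the four counts partition the set."""
    counts = {cat: 0 for cat in LoopTadCategory}
    for loop in loops:
        counts[classify_loop(loop, tads, mode)] += 1
    return counts


@dataclass
class ArchitectureSummary:
    n_loops: int
    n_tads: int
    mean_loop_size: float
    median_loop_size: float
    median_tad_size: float
    n_long_loops: int
    long_threshold: int
    per_chromosome: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_loops": [self.n_loops],
                "n_tads": [self.n_tads],
                "mean_loop_size": [self.mean_loop_size],
                "median_loop_size": [self.median_loop_size],
                "median_tad_size": [self.median_tad_size],
                "n_long_loops": [self.n_long_loops],
                "long_threshold": [self.long_threshold],
            }
        )


def summarize(
    loops: Sequence[Loop],
    tads: Sequence[TAD],
    long_threshold: int = DEFAULT_LONG_LOOP_THRESHOLD,
) -> ArchitectureSummary:
    """Descriptive loop/TAD statistics with a per-chromosome breakdown.

    ``n_long_loops`` counts loops whose size strictly exceeds the threshold
    (default 3 Mb).
    """
    loop_sizes = np.array([lp.size for lp in loops], dtype=float)
    tad_sizes = np.array([t.size for t in tads], dtype=float)
    chroms = sorted(
        {lp.chrom for lp in loops} | {t.chrom for t in tads}
    )
    rows = []
    for chrom in chroms:
        ls = np.array([lp.size for lp in loops if lp.chrom == chrom])
        ts = np.array([t.size for t in tads if t.chrom == chrom])
        rows.append(
            {
                "chrom": chrom,
                "n_loops": len(ls),
                "n_tads": len(ts),
                "mean_loop_size": float(np.mean(ls)) if len(ls) else np.nan,
                "median_loop_size": float(np.median(ls)) if len(ls) else np.nan,
                "median_tad_size": float(np.median(ts)) if len(ts) else np.nan,
                "n_long_loops": int(np.sum(ls > long_threshold)),
            }
        )
    per_chrom = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "n_loops",
            "n_tads",
            "mean_loop_size",
            "median_loop_size",
            "median_tad_size",
            "n_long_loops",
        ],
    )
    return ArchitectureSummary(
        n_loops=len(loops),
        n_tads=len(tads),
        mean_loop_size=float(np.mean(loop_sizes)) if len(loop_sizes) else np.nan,
        median_loop_size=float(np.median(loop_sizes)) if len(loop_sizes) else np.nan,
        median_tad_size=float(np.median(tad_sizes)) if len(tad_sizes) else np.nan,
        n_long_loops=int(np.sum(loop_sizes > long_threshold)),
        long_threshold=long_threshold,
        per_chromosome=per_chrom,
    )


@dataclass(frozen=True)
class SizeComparison:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int


def compare_sizes(a: Sequence[float], b: Sequence[float]) -> SizeComparison:
    """Two-sided Mann–Whitney U on two size samples.

    Uses the normal approximation with tie correction and continuity
    correction, the standard choice for loop/TAD size distributions.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return SizeComparison(
        statistic=float(res.statistic),
        pvalue=float(min(1.0, res.pvalue)),
        n_a=len(a),
        n_b=len(b),
    )


def compare_sizes_per_chromosome(
    a_by_chrom: Mapping[str, Sequence[float]],
    b_by_chrom: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-chromosome Mann–Whitney tests with Benjamini–Hochberg adjustment.

    Chromosomes empty in either condition are reported with NaN p-values and
    excluded from the adjustment family.
    """
    chroms = sorted(set(a_by_chrom) | set(b_by_chrom))
    rows = []
    for chrom in chroms:
        a = a_by_chrom.get(chrom, [])
        b = b_by_chrom.get(chrom, [])
        if len(a) and len(b):
            cmp = compare_sizes(a, b)
            rows.append((chrom, len(a), len(b), cmp.statistic, cmp.pvalue))
        else:
            rows.append((chrom, len(a), len(b), np.nan, np.nan))
    df = pd.DataFrame(rows, columns=["chrom", "n_a", "n_b", "statistic", "pvalue"])
    df["padj"] = np.nan
    tested = df["pvalue"].notna()
    if tested.any():
        df.loc[tested, "padj"] = multipletests(
            df.loc[tested, "pvalue"], method="fdr_bh"
        )[1]
    return df
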