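"""CTCF peak sharing, CTCF-bound loop anchors, methylation meta-profiles
and the expression x Pol II x CTCF gene-body cross-analysis.

Peak sharing uses merged-interval semantics: peaks are merged within each
set (>= 1 bp overlap merges; abutting intervals do not), the union across
sets is merged the same way, and each merged union event is labeled shared
when covered by at least one peak from every contributing set. The shared
percentage is 100 * shared / union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    Loop,
    Peak,
    SignalTrack,
    merge_intervals,
    overlap_length,
)

__all__ = [
    "SharingResult",
    "MetaProfile",
    "sharing_percent_from_counts",
    "classify_sharing",
    "three_way_sharing",
    "classify_loop_ctcf",
    "classify_loops_ctcf",
    "metaprofile",
    "cross_analysis",
]


def _as_intervals(peaks: Iterable[Peak | GenomicInterval]) -> list[GenomicInterval]:
    return [p.region if isinstance(p, Peak) else p for p in peaks]


@dataclass(frozen=True)
class SharingResult:
    """Peak sharing between two cell types over merged union events."""

    n_set1: int
    n_set2: int
    n_shared: int
    n_specific1: int
    n_specific2: int
    union: int
    percent_shared: float  # 100 * shared / union, 1 decimal place


def sharing_percent_from_counts(n1: int, n2: int, n_shared: int) -> float:
    """Shared percentage of the union under one-to-one peak matching:
    100 * shared / (n1 + n2 - shared), to one decimal place."""
    union = n1 + n2 - n_shared
    if union <= 0:
        raise ValueError("union must be positive")
    if n_shared > min(n1, n2):
        raise ValueError("shared count exceeds a set size")
    return round(100 * n_shared / union, 1)


def classify_sharing(
    set1: Iterable[Peak | GenomicInterval],
    set2: Iterable[Peak | GenomicInterval],
) -> tuple[SharingResult, list[tuple[GenomicInterval, str]]]:
    """Shared / set-specific peak census plus per-event labels.

    Returns the counts and a list of (merged union interval, label) with
    label in {shared, specific1, specific2}. Symmetric up to swapping the
    two specific counts.
    """
    iv1 = merge_intervals(_as_intervals(set1))
    iv2 = merge_intervals(_as_intervals(set2))
    union = merge_intervals(iv1 + iv2)
    labeled: list[tuple[GenomicInterval, str]] = []
    n_shared = n_sp1 = n_sp2 = 0
    for ev in union:
        hit1 = any(overlap_length(ev, a) > 0 for a in iv1)
        hit2 = any(overlap_length(ev, b) > 0 for b in iv2)
        if hit1 and hit2:
            label, n_shared = "shared", n_shared + 1
        elif hit1:
            label, n_sp1 = "specific1", n_sp1 + 1
        else:
            label, n_sp2 = "specific2", n_sp2 + 1
        labeled.append((ev, label))
    n_union = len(union)
    pct = round(100 * n_shared / n_union, 1) if n_union else 0.0
    return (
        SharingResult(
            n_set1=len(iv1),
            n_set2=len(iv2),
            n_shared=n_shared,
            n_specific1=n_sp1,
            n_specific2=n_sp2,
            union=n_union,
            percent_shared=pct,
        ),
        labeled,
    )


def three_way_sharing(
    sets: Mapping[str, Iterable[Peak | GenomicInterval]],
) -> dict[tuple[str, ...], int]:
    """Venn-style census of merged union events across three peak sets.

    Keys are sorted tuples of the set names covering each event (7 possible
    regions); values sum to the merged union size.
    """
    names = sorted(sets)
    if len(names) != 3:
        raise ValueError("exactly three named peak sets are required")
    merged = {name: merge_intervals(_as_intervals(sets[name])) for name in names}
    union = merge_intervals([iv for m in merged.values() for iv in m])
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, 4):
        for combo in combinations(names, r):
            counts[combo] = 0
    for ev in union:
        covering = tuple(
            name
            for name in names
            if any(overlap_length(ev, iv) > 0 for iv in merged[name])
        )
        counts[covering] += 1
    return counts


def classify_loop_ctcf(
    loop: Loop, peaks: Sequence[Peak | GenomicInterval], slack: int = 0
) -> int:
    """Number of loop anchors (0, 1 or 2) bound by a CTCF peak.

    An anchor is bound when at least one peak overlaps the anchor interval
    extended by ``slack`` bp on each side.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    ivs = _as_intervals(peaks)
    n = 0
    for anchor in (loop.anchor1, loop.anchor2):
        ext = anchor.padded(slack)
        if any(overlap_length(ext, p) > 0 for p in ivs):
            n += 1
    return n


def classify_loops_ctcf(
    loops: Iterable[Loop],
    peaks: Sequence[Peak | GenomicInterval],
    slack: int = 0,
) -> tuple[dict[int, int], dict[int, float]]:
    """Counts and proportions of loops with 0/1/2 CTCF-bound anchors."""
    counts = {0: 0, 1: 0, 2: 0}
    for loop in loops:
        counts[classify_loop_ctcf(loop, peaks, slack)] += 1
    total = sum(counts.values())
    props = {k: (v / total if total else math.nan) for k, v in counts.items()}
    return counts, props


@dataclass
class MetaProfile:
    """Mean signal as a function of offset from aligned peak centers.

    ``offsets`` are bin left edges in bp relative to the center, tiling
    [-flank, +flank); ``mean_value`` is NaN where no peak contributed.
    """

    offsets: np.ndarray
    mean_value: np.ndarray
    n_contributing: np.ndarray
    flank: int
    bin_size: int

    @property
    def center_index(self) -> int:
        """Index of the bin containing offset 0."""
        return int(np.searchsorted(self.offsets, 0, side="right") - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean_value": self.mean_value,
                "n_contributing": self.n_contributing,
            }
        )


def metaprofile(
    peaks: Sequence[Peak],
    track: SignalTrack,
    flank: int = 5000,
    bin_size: int = 100,
) -> MetaProfile:
    """Average a signal track around peak centers (summit when present,
    else interval midpoint), in fixed-width offset bins spanning +/- flank.

    Within a peak, each bin averages the overlapping track records weighted
    by overlap length; across peaks, the per-bin mean runs over peaks with
    at least one covered record in that bin.
    """
    if flank % bin_size != 0:
        raise ValueError(
            f"flank {flank} must be divisible by bin size {bin_size}"
        )
    n_bins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size, dtype=np.int64)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for pk in peaks:
        center = pk.center
        chrom = pk.region.chrom
        lo, hi = center - flank, center + flank
        s, e, v = track.query(chrom, max(0, lo), hi)
        if len(v) == 0:
            continue
        wsum = np.zeros(n_bins)
        wvsum = np.zeros(n_bins)
        for rs, re, rv in zip(s, e, v):
            b0 = max(0, (max(rs, lo) - lo) // bin_size)
            b1 = min(n_bins - 1, (min(re, hi) - 1 - lo) // bin_size)
            for b in range(int(b0), int(b1) + 1):
                bin_lo = lo + b * bin_size
                ov = min(re, bin_lo + bin_size) - max(rs, bin_lo)
                if ov > 0:
                    wsum[b] += ov
                    wvsum[b] += ov * rv
        covered = wsum > 0
        sums[covered] += wvsum[covered] / wsum[covered]
        counts[covered] += 1
    mean = np.full(n_bins, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return MetaProfile(offsets, mean, counts, flank, bin_size)


def cross_analysis(
    expression: pd.DataFrame,
    genes: Sequence[GeneModel],
    ctcf_tracks: Mapping[str, SignalTrack],
    polii_track: SignalTrack,
    rank_by: str,
    top_n: int = 100,
    coding_only: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Top-expressed genes joined with gene-body CTCF and Pol II signal.

    Genes are ranked by the ``rank_by`` expression column (descending FPKM,
    ties by gene_id); the top ``top_n`` are kept. Per gene the longest
    transcript is chosen (tie: lexicographically smallest transcript_id)
    and the length-weighted mean of each track over its body computed.
    Non-coding genes are dropped afterwards when ``coding_only``. Genes
    without a transcript model are excluded with a census warning.
    """
    if rank_by not in expression.columns:
        raise ValueError(f"expression table lacks column {rank_by!r}")
    ranked = expression.sort_values(
        by=[rank_by], ascending=False, kind="mergesort"
    )
    ranked = ranked.loc[
        sorted(ranked.index, key=lambda g: (-ranked.at[g, rank_by], g))
    ]
    top_ids = list(ranked.index[:top_n])

    by_gene: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_gene.setdefault(g.gene_id, []).append(g)

    warnings: list[str] = []
    rows = []
    for rank, gene_id in enumerate(top_ids, start=1):
        models = by_gene.get(gene_id)
        if not models:
            warnings.append(f"gene {gene_id} has no transcript model; excluded")
            continue
        tx = min(models, key=lambda m: (-m.length, m.transcript_id))
        if coding_only and not tx.coding:
            continue
        row = {
            "gene_id": gene_id,
            "rank": rank,
            "expression": float(ranked.at[gene_id, rank_by]),
            "transcript_id": tx.transcript_id,
            "transcript_length": tx.length,
            "coding": tx.coding,
        }
        for cell, track in ctcf_tracks.items():
            row[f"ctcf_{cell}_mean"] = track.mean_over(
                tx.chrom, tx.tx_start, tx.tx_end
            )
        row["polii_mean"] = polii_track.mean_over(tx.chrom, tx.tx_start, tx.tx_end)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("rank").reset_index(drop=True)
    return df, warnings
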