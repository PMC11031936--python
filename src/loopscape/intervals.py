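"""Core genomic-interval data model, overlap engine and file readers/writers.

Every coordinate in this package is 0-based, half-open (BED convention).
Readers for 1-based dialects (refFlat-style gene tables) convert at the
boundary, so downstream code never sees a 1-based coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "ParseError",
    "GenomicInterval",
    "Loop",
    "TAD",
    "Peak",
    "SignalTrack",
    "ContactStats",
    "ContactSummary",
    "GeneModel",
    "LoopParseResult",
    "overlap_length",
    "find_overlaps",
    "merge_intervals",
    "sort_key",
    "read_loops",
    "write_loops",
    "read_intervals",
    "write_bed",
    "write_narrowpeak",
    "write_bedgraph",
    "read_genes_bed12",
    "read_genes_refflat",
    "read_expression",
    "read_gmt",
    "read_contact_stats",
    "aggregate_contact_stats",
]


class ParseError(ValueError):
    """A record in an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic region, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Chromosome name, kept verbatim (no ``chr`` aliasing).
    start, end : int
        0-based inclusive start, exclusive end; ``start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    name, score : optional label and numeric score.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def padded(self, pad: int) -> "GenomicInterval":
        """Extend by ``pad`` bp on each side, clipped at zero."""
        return replace(self, start=max(0, self.start - pad), end=self.end + pad)


def sort_key(iv: GenomicInterval) -> tuple:
    """Deterministic ordering: (chrom lexicographic, start, end, name)."""
    return (iv.chrom, iv.start, iv.end, iv.name or "")


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: an ordered pair of same-chromosome anchors.

    ``anchor1`` precedes ``anchor2`` by midpoint; loop size is the distance
    between anchor midpoints, which is well defined even for unequal anchor
    widths. Extra columns from the source file are carried opaquely.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    extras: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if not self.anchor1.midpoint < self.anchor2.midpoint:
            raise ValueError("anchor1 midpoint must precede anchor2 midpoint")

    @classmethod
    def from_anchors(
        cls,
        a: GenomicInterval,
        b: GenomicInterval,
        extras: tuple[str, ...] = (),
    ) -> "Loop":
        """Build a loop, swapping anchors if needed to satisfy the ordering."""
        if a.midpoint > b.midpoint:
            a, b = b, a
        return cls(a, b, extras)

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def size(self) -> float:
        return self.anchor2.midpoint - self.anchor1.midpoint


@dataclass(frozen=True)
class TAD:
    """A topologically associated domain."""

    region: GenomicInterval

    @property
    def size(self) -> int:
        return self.region.length

    @property
    def chrom(self) -> str:
        return self.region.chrom


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak with optional summit offset (bp from start)."""

    region: GenomicInterval
    summit_offset: int | None = None
    signal: float | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.region.length
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of length "
                f"{self.region.length}"
            )

    @property
    def center(self) -> int:
        """Summit position when known, else the interval midpoint."""
        if self.summit_offset is not None:
            return self.region.start + self.summit_offset
        return int(self.region.midpoint)


class SignalTrack:
    """A sorted, non-overlapping scalar signal track (bedGraph semantics).

    Stores per-chromosome numpy arrays for fast range queries; bases not
    covered by any record carry no value (they are *not* zero).
    """

    def __init__(self, records: Iterable[tuple[GenomicInterval, float]]):
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in records:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self.n_records = 0
        for chrom in sorted(by_chrom):
            recs = sorted(by_chrom[chrom])
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            if len(recs) > 1 and np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ParseError(
                    f"overlapping records on {chrom} near position {starts[i + 1]}"
                )
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = np.array([r[2] for r in recs], dtype=float)
            self.n_records += len(recs)

    @property
    def chroms(self) -> list[str]:
        return list(self._starts)

    def query(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (starts, ends, values) of records overlapping [start, end)."""
        if chrom not in self._starts:
            empty = np.empty(0)
            return empty.astype(np.int64), empty.astype(np.int64), empty
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return starts[lo:hi], ends[lo:hi], values[lo:hi]

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Overlap-length-weighted mean over [start, end); NaN when uncovered."""
        s, e, v = self.query(chrom, start, end)
        if len(v) == 0:
            return math.nan
        w = np.minimum(e, end) - np.maximum(s, start)
        return float(np.sum(w * v) / np.sum(w))

    def iter_records(self) -> Iterator[tuple[GenomicInterval, float]]:
        for chrom in self._starts:
            for s, e, v in zip(
                self._starts[chrom], self._ends[chrom], self._values[chrom]
            ):
                yield GenomicInterval(chrom, int(s), int(e)), float(v)


@dataclass(frozen=True)
class ContactStats:
    """Hi-C contact QC counts for one sample."""

    sample: str
    total_contacts: float
    inter_chromosomal_fraction: float

    def __post_init__(self) -> None:
        if self.total_contacts < 0:
            raise ValueError("total_contacts must be >= 0")
        if not 0 <= self.inter_chromosomal_fraction <= 1:
            raise ValueError("inter_chromosomal_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ContactSummary:
    total_contacts: float
    total_millions: float
    total_billions: float  # rounded to 2 decimals
    n_samples: int


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with strand-aware TSS and exon structure."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = ()
    coding: bool = True

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError("tx_start must be < tx_end")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start: tx_start on +, tx_end on − strand."""
        if self.strand == "+":
            return self.tx_start
        if self.strand == "-":
            return self.tx_end
        raise ValueError(f"TSS undefined for unstranded gene {self.gene_id}")

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.tx_start, self.tx_end, self.strand, self.transcript_id
        )


# ---------------------------------------------------------------------------
# Overlap algebra
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two half-open intervals."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def find_overlaps(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """Index pairs (qi, si) with positive overlap.

    Ordered by query position, then by subject coordinate
    (chrom, start, end, name). Matches a brute-force all-against-all scan.
    """
    trees: dict[str, IntervalTree] = {}
    for si, iv in enumerate(subject):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, si)
    pairs: list[tuple[int, int]] = []
    for qi, q in enumerate(query):
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        hits = [h.data for h in tree.overlap(q.start, q.end)]
        hits.sort(key=lambda si: sort_key(subject[si]) + (si,))
        pairs.extend((qi, si) for si in hits)
    return pairs


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Merge intervals overlapping by >= 1 bp; abutting intervals stay apart."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=sort_key):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end)
            )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

@dataclass
class LoopParseResult:
    """Loops read from a BEDPE-dialect file plus a skip census."""

    loops: list[Loop]
    n_skipped_interchromosomal: int = 0
    warnings: list[str] = field(default_factory=list)


def _parse_int(token: str, path, lineno: int, what: str) -> int:
    try:
        return int(float(token)) if "." in token else int(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: malformed {what} coordinate {token!r}"
        ) from None


def read_loops(path, dialect: str = "hiccups_bedpe") -> LoopParseResult:
    """Read a loop list in HiCCUPS BEDPE dialect (chr1,x1,x2,chr2,y1,y2,...).

    Anchors are ordered by midpoint. Inter-chromosomal records are skipped
    with a warning recorded in the census, never returned. A leading header
    line whose second token is not an integer is skipped silently, as are
    ``#`` comment lines.
    """
    if dialect not in ("hiccups_bedpe", "plain_bedpe"):
        raise ValueError(f"unknown BEDPE dialect {dialect!r}")
    result = LoopParseResult(loops=[])
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 columns")
            # HiCCUPS writes one header row; recognise it by a non-numeric
            # coordinate column in the first data position.
            if lineno == 1 and not _is_int(fields[1]):
                continue
            c1 = fields[0]
            x1 = _parse_int(fields[1], path, lineno, "x1")
            x2 = _parse_int(fields[2], path, lineno, "x2")
            c2 = fields[3]
            y1 = _parse_int(fields[4], path, lineno, "y1")
            y2 = _parse_int(fields[5], path, lineno, "y2")
            if c1 != c2:
                result.n_skipped_interchromosomal += 1
                result.warnings.append(
                    f"{path}:{lineno}: inter-chromosomal record {c1}/{c2} skipped"
                )
                continue
            a = GenomicInterval(c1, x1, x2)
            b = GenomicInterval(c2, y1, y2)
            result.loops.append(Loop.from_anchors(a, b, tuple(fields[6:])))
    return result


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def write_loops(path, loops: Iterable[Loop]) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            cols = [
                lp.anchor1.chrom,
                str(lp.anchor1.start),
                str(lp.anchor1.end),
                lp.anchor2.chrom,
                str(lp.anchor2.start),
                str(lp.anchor2.end),
                *lp.extras,
            ]
            fh.write("\t".join(cols) + "\n")


_BED_FORMATS = ("bed3", "bed6", "bed12", "narrowPeak", "bedGraph")


def read_intervals(path, format: str = "bed3"):
    """Read a BED-family file into the matching domain objects.

    Returns a list of :class:`GenomicInterval` (bed3/bed6/bed12), a list of
    :class:`Peak` (narrowPeak; column 10 of −1 means no summit) or a
    :class:`SignalTrack` (bedGraph, validated sorted and non-overlapping).
    """
    if format not in _BED_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_BED_FORMATS}")
    rows = _read_rows(path)
    if format == "bedGraph":
        records = []
        for lineno, fields in rows:
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            iv = _make_interval(fields, path, lineno)
            records.append((iv, float(fields[3])))
        return SignalTrack(records)
    if format == "narrowPeak":
        peaks = []
        for lineno, fields in rows:
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: narrowPeak needs 10 columns")
            iv = _make_interval(fields, path, lineno)
            iv = replace(
                iv,
                strand=fields[5] if fields[5] in "+-" else ".",
                name=None if fields[3] == "." else fields[3],
            )
            summit = int(fields[9])
            peaks.append(
                Peak(
                    iv,
                    summit_offset=None if summit < 0 else summit,
                    signal=float(fields[6]),
                )
            )
        return peaks
    n_min = {"bed3": 3, "bed6": 6, "bed12": 12}[format]
    out = []
    for lineno, fields in rows:
        if len(fields) < n_min:
            raise ParseError(f"{path}:{lineno}: {format} needs {n_min} columns")
        iv = _make_interval(fields, path, lineno)
        if n_min >= 6:
            iv = replace(
                iv,
                name=None if fields[3] == "." else fields[3],
                score=None if fields[4] == "." else float(fields[4]),
                strand=fields[5] if fields[5] in "+-" else ".",
            )
        out.append(iv)
    return out


def _read_rows(path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append((lineno, line.split("\t") if "\t" in line else line.split()))
    return rows


def _make_interval(fields: list[str], path, lineno: int) -> GenomicInterval:
    start = _parse_int(fields[1], path, lineno, "start")
    end = _parse_int(fields[2], path, lineno, "end")
    if start >= end:
        raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
    return GenomicInterval(fields[0], start, end)


def write_bed(path, intervals: Iterable[GenomicInterval], columns: int = 6) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if columns >= 6:
                row += [
                    iv.name or ".",
                    "." if iv.score is None else _fmt_num(iv.score),
                    iv.strand,
                ]
            fh.write("\t".join(row) + "\n")


def write_narrowpeak(path, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.region
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        "0",
                        iv.strand,
                        _fmt_num(pk.signal if pk.signal is not None else 0),
                        "-1",
                        "-1",
                        str(-1 if pk.summit_offset is None else pk.summit_offset),
                    ]
                )
                + "\n"
            )


def write_bedgraph(path, track: SignalTrack, fmt: str = "%.4f") -> None:
    with open(path, "w") as fh:
        for iv, value in track.iter_records():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{fmt % value}\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_genes_bed12(path) -> list[GeneModel]:
    """Read BED12 gene models; name column ``gene_id|transcript_id``.

    A name without ``|`` serves as both ids. Coding status follows the
    thick region (thickStart < thickEnd).
    """
    genes = []
    for lineno, fields in _read_rows(path):
        if len(fields) < 12:
            raise ParseError(f"{path}:{lineno}: bed12 needs 12 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], path, lineno, "start")
        end = _parse_int(fields[2], path, lineno, "end")
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        name = fields[3]
        gene_id, _, transcript_id = name.partition("|")
        strand = fields[5]
        thick_start = _parse_int(fields[6], path, lineno, "thickStart")
        thick_end = _parse_int(fields[7], path, lineno, "thickEnd")
        n_blocks = int(fields[9])
        sizes = [int(t) for t in fields[10].rstrip(",").split(",")]
        offsets = [int(t) for t in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ParseError(f"{path}:{lineno}: block count mismatch")
        exons = tuple(
            (start + off, start + off + size) for off, size in zip(offsets, sizes)
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=transcript_id or name,
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
                exons=exons,
                coding=thick_start < thick_end,
            )
        )
    return genes


def read_genes_refflat(path) -> list[GeneModel]:
    """Read a refFlat-style table (geneName, name, chrom, strand, txStart,
    txEnd, cdsStart, cdsEnd, exonCount, exonStarts, exonEnds), treating
    txStart/exonStarts as 1-based inclusive and converting to 0-based
    half-open at this boundary."""
    genes = []
    for lineno, fields in _read_rows(path):
        if len(fields) < 11:
            raise ParseError(f"{path}:{lineno}: refFlat needs 11 columns")
        tx_start = _parse_int(fields[4], path, lineno, "txStart") - 1
        tx_end = _parse_int(fields[5], path, lineno, "txEnd")
        cds_start = _parse_int(fields[6], path, lineno, "cdsStart") - 1
        cds_end = _parse_int(fields[7], path, lineno, "cdsEnd")
        ex_starts = [int(t) - 1 for t in fields[9].rstrip(",").split(",")]
        ex_ends = [int(t) for t in fields[10].rstrip(",").split(",")]
        genes.append(
            GeneModel(
                gene_id=fields[0],
                transcript_id=fields[1],
                chrom=fields[2],
                strand=fields[3],
                tx_start=tx_start,
                tx_end=tx_end,
                exons=tuple(zip(ex_starts, ex_ends)),
                coding=cds_start < cds_end,
            )
        )
    return genes


def read_expression(path) -> pd.DataFrame:
    """Read a TSV of gene_id x FPKM-per-cell-type, indexed by gene_id."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id'")
    return df.set_index("gene_id")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, then member genes."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT needs >= 3 columns")
            terms[fields[0]] = {g for g in fields[2:] if g}
    return terms


def read_contact_stats(path) -> list[ContactStats]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "total_contacts", "inter_chromosomal_fraction"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
    return [
        ContactStats(
            str(r["sample"]),
            float(r["total_contacts"]),
            float(r["inter_chromosomal_fraction"]),
        )
        for _, r in df.iterrows()
    ]


def aggregate_contact_stats(stats: Sequence[ContactStats]) -> ContactSummary:
    """Sum per-sample contact counts; billions reported to 2 decimals."""
    if len(stats) == 0:
        raise ValueError("at least one ContactStats record is required")
    total = float(sum(s.total_contacts for s in stats))
    return ContactSummary(
        total_contacts=total,
        total_millions=round(total / 1e6, 2),
        total_billions=round(total / 1e9, 2),
        n_samples=len(stats),
    )
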