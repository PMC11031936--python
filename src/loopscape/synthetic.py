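"""Seeded generator of a coherent toy feature universe with a ground-truth
ledger.

The generator emits, for two cell types (``epi`` and ``fib``), every
standard-format file the pipeline consumes: TAD calls (BED), loop lists
(BEDPE), CTCF peaks (narrowPeak), compartment eigenvector tracks
(bedGraph), per-CpG methylation tracks (bedGraph), gene-body Pol II and
CTCF coverage tracks (bedGraph), gene models (BED12) and an expression
table (TSV) — plus a ``truth.json`` ledger recording the planted label of
every feature, so downstream classifiers can be scored exactly.

Planted structure, by construction:

* TADs tile each chromosome left to right with log-normal sizes and gaps
  between them; a TAD may receive one nested child (depth <= 2), strictly
  inside its parent.
* Loops are planted in four categories relative to the cell's TADs under
  the anchor-midpoint containment rule: intra (both midpoints in one TAD),
  inter (midpoints in two distinct TADs), one_anchor, not_in_tad (gaps).
* CTCF peaks sit at loop anchors with a configurable probability, plus
  background peaks planted with cell-type membership epi_only / fib_only /
  shared (shared peaks appear in both cell files at identical coordinates).
* The eigenvector track alternates +/- pc_magnitude in fixed-size blocks;
  gene promoters are placed wholly inside their assigned block, so
  compartment recovery is exact for non-boundary genes.
* Expression is log-normal keyed to the compartment label (FPKM = 2^x with
  x ~ Normal), elevated in compartment A; a few "crystallin-like" genes get
  very high expression in fiber cells.
* Methylation sits at a constant baseline on a regular CpG grid except for
  linear dips centered on each CTCF peak.
* Pol II (and per-cell CTCF) coverage over each gene body is proportional
  to that gene's expression.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .intervals import (
    GeneModel,
    GenomicInterval,
    Loop,
    Peak,
    SignalTrack,
    TAD,
    write_bed,
    write_bedgraph,
    write_loops,
    write_narrowpeak,
)

__all__ = ["SimConfig", "SyntheticTruth", "SimulationError", "generate", "CELLS"]

CELLS = ("epi", "fib")

LOOP_CATEGORIES = ("intra", "inter", "one_anchor", "not_in_tad")


class SimulationError(RuntimeError):
    """The requested feature universe cannot be placed on the given genome."""


@dataclass
class SimConfig:
    """Parameters of the synthetic feature universe.

    Sizes are in bp; expression parameters are on the log2(FPKM) scale.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 6_000_000, "chr2": 4_000_000}
    )
    # TAD sizes are log-normal: ln(size) ~ Normal(log_mean, log_sd)
    tad_size_log_mean: float = math.log(200_000)
    tad_size_log_sd: float = 0.5
    nesting_prob: float = 0.3
    n_loops: dict[str, int] = field(
        default_factory=lambda: {
            "intra": 60, "inter": 25, "one_anchor": 20, "not_in_tad": 15,
        }
    )
    anchor_width: int = 10_000
    ctcf_at_anchor_prob: float = 0.6
    # background (non-anchor) peaks planted with cell-type membership
    n_peaks_epi_only: int = 30
    n_peaks_fib_only: int = 50
    n_peaks_shared: int = 20
    peak_width: int = 400
    compartment_block_size: int = 1_000_000
    pc_bin_size: int = 10_000
    pc_magnitude: float = 2.0
    n_genes: int = 300
    n_crystallin: int = 8
    n_boundary_genes: int = 0  # promoters straddling a compartment boundary
    frac_noncoding: float = 0.15
    expr_log2_mean_A: float = 5.0
    expr_log2_mean_B: float = 3.0
    expr_log2_sd: float = 1.0
    expr_log2_crystallin: float = 12.0
    meth_baseline: float = 0.8
    meth_dip_depth: float = 0.7
    meth_dip_halfwidth: int = 500
    cpg_spacing: int = 50
    seed: int = 0

    @property
    def n_background_peaks(self) -> int:
        return self.n_peaks_epi_only + self.n_peaks_fib_only + self.n_peaks_shared

    def validate(self) -> None:
        for name in ("nesting_prob", "ctcf_at_anchor_prob", "frac_noncoding"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "anchor_width", "peak_width", "compartment_block_size",
            "pc_bin_size", "cpg_spacing", "meth_dip_halfwidth",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.chrom_sizes or any(s <= 0 for s in self.chrom_sizes.values()):
            raise ValueError("chrom_sizes must be positive")
        if set(self.n_loops) - set(LOOP_CATEGORIES):
            raise ValueError(f"unknown loop categories in {self.n_loops}")
        if self.expr_log2_mean_A <= self.expr_log2_mean_B:
            raise ValueError("expr_log2_mean_A must exceed expr_log2_mean_B")
        if not 0 <= self.meth_baseline <= 1:
            raise ValueError("meth_baseline must be in [0, 1]")
        if not 0 <= self.meth_dip_depth <= self.meth_baseline:
            raise ValueError("meth_dip_depth must be in [0, meth_baseline]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ledger of every planted feature and its label.

    ``loops[cell]`` lists dicts with the planted category and anchor
    coordinates; ``peaks`` lists dicts with origin (anchor/background) and
    membership (epi_only/fib_only/shared); ``genes`` lists dicts with the
    planted compartment label, coding/crystallin/boundary flags and FPKM
    per cell; ``meth_dip_centers[cell]`` lists peak-center positions.
    """

    config: dict
    tads: dict[str, list[dict]] = field(default_factory=dict)
    loops: dict[str, list[dict]] = field(default_factory=dict)
    peaks: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    compartment_blocks: list[dict] = field(default_factory=list)
    meth_dip_centers: dict[str, list[dict]] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    def loop_category_counts(self, cell: str) -> dict[str, int]:
        counts = {cat: 0 for cat in LOOP_CATEGORIES}
        for rec in self.loops[cell]:
            counts[rec["category"]] += 1
        return counts

    def peak_membership_counts(self) -> dict[str, int]:
        counts = {"epi_only": 0, "fib_only": 0, "shared": 0}
        for rec in self.peaks:
            if rec["origin"] == "background":
                counts[rec["membership"]] += 1
        return counts

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _grid(cfg: SimConfig, pos: float) -> int:
    """Snap a position to the CpG grid so peak centers sit on grid points."""
    return int(round(pos / cfg.cpg_spacing) * cfg.cpg_spacing)


def _make_tads(cfg: SimConfig, rng: np.random.Generator):
    """Tile each chromosome with top-level TADs separated by gaps; some
    TADs receive one strictly nested child."""
    top: list[GenomicInterval] = []
    nested: list[GenomicInterval] = []
    gaps: list[GenomicInterval] = []
    for chrom in sorted(cfg.chrom_sizes):
        size_limit = cfg.chrom_sizes[chrom]
        cursor = int(rng.integers(10_000, 40_000))
        if cursor > 0:
            gaps.append(GenomicInterval(chrom, 0, cursor))
        while True:
            size = int(
                np.clip(
                    rng.lognormal(cfg.tad_size_log_mean, cfg.tad_size_log_sd),
                    60_000,
                    1_500_000,
                )
            )
            if cursor + size > size_limit - 10_000:
                if cursor < size_limit:
                    gaps.append(GenomicInterval(chrom, cursor, size_limit))
                break
            tad = GenomicInterval(chrom, cursor, cursor + size)
            top.append(tad)
            if rng.random() < cfg.nesting_prob and size > 150_000:
                child_len = int(size * rng.uniform(0.25, 0.45))
                child_start = cursor + int(
                    rng.uniform(0.1, 0.5) * (size - child_len)
                )
                nested.append(
                    GenomicInterval(chrom, child_start, child_start + child_len)
                )
            gap = int(rng.integers(20_000, 60_000))
            gaps.append(
                GenomicInterval(
                    chrom, cursor + size, min(cursor + size + gap, size_limit)
                )
            )
            cursor += size + gap
    return top, nested, gaps


def _place_loop_midpoints(
    cfg: SimConfig,
    rng: np.random.Generator,
    category: str,
    top: list[GenomicInterval],
    gaps: list[GenomicInterval],
) -> tuple[str, int, int]:
    """Two anchor-midpoint positions satisfying the category's definition."""
    w = cfg.anchor_width
    margin = w // 2 + cfg.cpg_spacing

    def inside(iv: GenomicInterval) -> int | None:
        lo, hi = iv.start + margin, iv.end - margin
        if hi - lo < 2 * cfg.cpg_spacing:
            return None
        return _grid(cfg, rng.integers(lo, hi))

    for _ in range(500):
        if category == "intra":
            cand = [t for t in top if t.length > 2 * w + 4 * margin]
            if not cand:
                break
            tad = cand[int(rng.integers(len(cand)))]
            m1, m2 = inside(tad), inside(tad)
            if m1 is None or m2 is None or abs(m2 - m1) < w + cfg.cpg_spacing:
                continue
            return tad.chrom, min(m1, m2), max(m1, m2)
        if category == "inter":
            by_chrom: dict[str, list[GenomicInterval]] = {}
            for t in top:
                by_chrom.setdefault(t.chrom, []).append(t)
            chroms = [c for c, ts in sorted(by_chrom.items()) if len(ts) >= 2]
            if not chroms:
                break
            chrom = chroms[int(rng.integers(len(chroms)))]
            ts = by_chrom[chrom]
            i, j = rng.choice(len(ts), size=2, replace=False)
            m1, m2 = inside(ts[int(i)]), inside(ts[int(j)])
            if m1 is None or m2 is None or m1 == m2:
                continue
            return chrom, min(m1, m2), max(m1, m2)
        if category == "one_anchor":
            by_chrom_t: dict[str, list] = {}
            for t in top:
                by_chrom_t.setdefault(t.chrom, []).append(t)
            usable_gaps = [
                g for g in gaps
                if g.length > 2 * margin + 2 * cfg.cpg_spacing
                and g.chrom in by_chrom_t
            ]
            if not usable_gaps:
                break
            gap = usable_gaps[int(rng.integers(len(usable_gaps)))]
            tads_c = by_chrom_t[gap.chrom]
            tad = tads_c[int(rng.integers(len(tads_c)))]
            m1, m2 = inside(tad), inside(gap)
            if m1 is None or m2 is None or m1 == m2:
                continue
            return gap.chrom, min(m1, m2), max(m1, m2)
        if category == "not_in_tad":
            by_chrom_g: dict[str, list] = {}
            for g in gaps:
                if g.length > 2 * margin + 2 * cfg.cpg_spacing:
                    by_chrom_g.setdefault(g.chrom, []).append(g)
            chroms = [c for c, gs in sorted(by_chrom_g.items()) if len(gs) >= 2]
            if not chroms:
                break
            chrom = chroms[int(rng.integers(len(chroms)))]
            gs = by_chrom_g[chrom]
            i, j = rng.choice(len(gs), size=2, replace=False)
            m1, m2 = inside(gs[int(i)]), inside(gs[int(j)])
            if m1 is None or m2 is None or m1 == m2:
                continue
            return chrom, min(m1, m2), max(m1, m2)
    raise SimulationError(
        f"cannot place a {category!r} loop on this genome "
        "(category counts unsatisfiable)"
    )


def _compartment_blocks(cfg: SimConfig) -> list[dict]:
    blocks = []
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        start, idx = 0, 0
        while start < size:
            end = min(start + cfg.compartment_block_size, size)
            label = "A" if idx % 2 == 0 else "B"
            blocks.append(
                {"chrom": chrom, "start": start, "end": end, "label": label}
            )
            start, idx = end, idx + 1
    return blocks


def generate(config: SimConfig, outdir) -> SyntheticTruth:
    """Generate the feature universe, write all files under ``outdir`` and
    return the ground-truth ledger (also written as ``truth.json``).

    A fixed seed yields byte-identical files across runs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth(config=config.to_dict())

    # --- TADs and loops, per cell -------------------------------------
    tads_by_cell: dict[str, list[GenomicInterval]] = {}
    anchor_peak_centers: dict[str, list[int | str]] = {}
    peaks_by_cell: dict[str, list[Peak]] = {c: [] for c in CELLS}
    w = config.anchor_width
    for cell in CELLS:
        top, nested, gaps = _make_tads(config, rng)
        all_tads = sorted(top + nested, key=lambda t: (t.chrom, t.start, t.end))
        tads_by_cell[cell] = all_tads
        truth.tads[cell] = [
            {"chrom": t.chrom, "start": t.start, "end": t.end,
             "level": "nested" if t in nested else "top"}
            for t in all_tads
        ]
        loops = []
        loop_recs = []
        for category in LOOP_CATEGORIES:
            for _ in range(config.n_loops.get(category, 0)):
                chrom, m1, m2 = _place_loop_midpoints(
                    config, rng, category, top, gaps
                )
                a1 = GenomicInterval(chrom, m1 - w // 2, m1 + w // 2)
                a2 = GenomicInterval(chrom, m2 - w // 2, m2 + w // 2)
                loops.append(Loop(a1, a2))
                loop_recs.append(
                    {
                        "category": category,
                        "chrom": chrom,
                        "m1": m1,
                        "m2": m2,
                        "anchor1": [a1.start, a1.end],
                        "anchor2": [a2.start, a2.end],
                    }
                )
                for m in (m1, m2):
                    if rng.random() < config.ctcf_at_anchor_prob:
                        half = config.peak_width // 2
                        pk = Peak(
                            GenomicInterval(
                                chrom, m - half, m + half,
                                name=f"{cell}_anchor_{len(peaks_by_cell[cell])}",
                            ),
                            summit_offset=half,
                            signal=float(np.round(rng.uniform(5, 30), 3)),
                        )
                        peaks_by_cell[cell].append(pk)
                        truth.peaks.append(
                            {
                                "origin": "anchor",
                                "membership": f"{cell}_only",
                                "chrom": chrom,
                                "start": pk.region.start,
                                "end": pk.region.end,
                                "center": m,
                            }
                        )
        truth.loops[cell] = loop_recs
        tad_path = outdir / f"tads_{cell}.bed"
        write_bed(tad_path, all_tads, columns=3)
        loops_path = outdir / f"loops_{cell}.bedpe"
        write_loops(loops_path, loops)
        truth.files[f"tads_{cell}"] = str(tad_path)
        truth.files[f"loops_{cell}"] = str(loops_path)

    # --- background peaks with planted sharing membership -------------
    chroms = sorted(config.chrom_sizes)
    occupied: list[tuple[str, int]] = [
        (rec["chrom"], rec["center"]) for rec in truth.peaks
    ]
    min_sep = max(
        3 * config.peak_width, 2 * config.meth_dip_halfwidth + 4 * config.cpg_spacing
    )

    def free(chrom: str, center: int) -> bool:
        return all(
            c != chrom or abs(center - m) >= min_sep for c, m in occupied
        )

    membership_plan = (
        [("epi_only", ("epi",))] * config.n_peaks_epi_only
        + [("fib_only", ("fib",))] * config.n_peaks_fib_only
        + [("shared", CELLS)] * config.n_peaks_shared
    )
    half = config.peak_width // 2
    for idx, (membership, cells) in enumerate(membership_plan):
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            center = _grid(
                config,
                rng.integers(half + min_sep, config.chrom_sizes[chrom] - half - min_sep),
            )
            if free(chrom, center):
                break
        else:
            raise SimulationError("cannot place background peaks without collision")
        occupied.append((chrom, center))
        for cell in cells:
            peaks_by_cell[cell].append(
                Peak(
                    GenomicInterval(
                        chrom, center - half, center + half,
                        name=f"bg_{membership}_{idx}",
                    ),
                    summit_offset=half,
                    signal=float(np.round(rng.uniform(5, 30), 3)),
                )
            )
        truth.peaks.append(
            {
                "origin": "background",
                "membership": membership,
                "chrom": chrom,
                "start": center - half,
                "end": center + half,
                "center": center,
            }
        )
    for cell in CELLS:
        pk_path = outdir / f"ctcf_{cell}.narrowPeak"
        write_narrowpeak(
            pk_path, sorted(peaks_by_cell[cell], key=lambda p: (p.region.chrom, p.region.start))
        )
        truth.files[f"ctcf_{cell}"] = str(pk_path)

    # --- compartments --------------------------------------------------
    blocks = _compartment_blocks(config)
    truth.compartment_blocks = blocks
    pc_records = []
    for b in blocks:
        value = config.pc_magnitude if b["label"] == "A" else -config.pc_magnitude
        start = b["start"]
        while start < b["end"]:
            end = min(start + config.pc_bin_size, b["end"])
            pc_records.append((GenomicInterval(b["chrom"], start, end), value))
            start = end
    pc_track = SignalTrack(pc_records)
    for cell in CELLS:
        pc_path = outdir / f"pc1_{cell}.bedgraph"
        write_bedgraph(pc_path, pc_track)
        truth.files[f"pc1_{cell}"] = str(pc_path)

    # --- genes and expression ------------------------------------------
    genes, gene_truth = _make_genes(config, rng, blocks)
    genes_path = outdir / "genes.bed12"
    _write_bed12(genes_path, genes)
    truth.files["genes"] = str(genes_path)

    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene_id\tepi\tfib\n")
        for rec in gene_truth:
            fh.write(
                f"{rec['gene_id']}\t{rec['fpkm']['epi']:.6g}\t{rec['fpkm']['fib']:.6g}\n"
            )
    truth.genes = gene_truth
    truth.files["expression"] = str(expr_path)

    # --- coverage tracks (Pol II, per-cell CTCF) -----------------------
    polii_records = []
    ctcf_cov_records: dict[str, list] = {c: [] for c in CELLS}
    for rec in gene_truth:
        body = GenomicInterval(rec["chrom"], rec["tx_start"], rec["tx_end"])
        polii_records.append((body, round(0.01 * rec["fpkm"]["fib"], 4)))
        for cell in CELLS:
            ctcf_cov_records[cell].append(
                (body, round(0.01 * rec["fpkm"][cell], 4))
            )
    polii_path = outdir / "polII.bedgraph"
    write_bedgraph(polii_path, SignalTrack(polii_records))
    truth.files["polII"] = str(polii_path)
    for cell in CELLS:
        p = outdir / f"ctcf_cov_{cell}.bedgraph"
        write_bedgraph(p, SignalTrack(ctcf_cov_records[cell]))
        truth.files[f"ctcf_cov_{cell}"] = str(p)

    # --- methylation ----------------------------------------------------
    for cell in CELLS:
        centers_by_chrom: dict[str, list[int]] = {}
        dips = []
        for rec in truth.peaks:
            if rec["membership"] in (f"{cell}_only", "shared"):
                centers_by_chrom.setdefault(rec["chrom"], []).append(rec["center"])
                dips.append({"chrom": rec["chrom"], "center": rec["center"]})
        truth.meth_dip_centers[cell] = dips
        meth_path = outdir / f"meth_{cell}.bedgraph"
        _write_methylation(config, meth_path, centers_by_chrom)
        truth.files[f"meth_{cell}"] = str(meth_path)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    truth.to_json(outdir / "truth.json")
    return truth


_MAX_GENE_LEN = 20_000
_GENE_MARGIN = 3000  # keeps the 2 kb promoter inside the block


def _make_genes(cfg: SimConfig, rng: np.random.Generator, blocks: list[dict]):
    """Place non-overlapping genes with promoters wholly inside compartment
    blocks and draw per-cell expression keyed to the planted label.

    Placement uses pre-computed slots per compartment label (one gene per
    slot, shuffled), so packing succeeds deterministically up to the slot
    capacity of the genome.
    """
    pitch = _MAX_GENE_LEN + 2 * _GENE_MARGIN + 1000
    slots: dict[str, list[tuple[str, int]]] = {"A": [], "B": []}
    for b in blocks:
        pos = b["start"] + _GENE_MARGIN
        while pos + _MAX_GENE_LEN + _GENE_MARGIN <= b["end"]:
            slots[b["label"]].append((b["chrom"], pos))
            pos += pitch
    for label in slots:
        rng.shuffle(slots[label])

    n_regular = cfg.n_genes - cfg.n_crystallin - cfg.n_boundary_genes
    if n_regular < 0:
        raise ValueError("n_genes too small for crystallin/boundary genes")
    plan: list[tuple[str, bool, bool]] = []  # (label, crystallin, boundary)
    plan += [("A", True, False)] * cfg.n_crystallin
    plan += [("A" if i % 2 == 0 else "B", False, False) for i in range(n_regular)]
    plan += [
        ("A" if i % 2 == 0 else "B", False, True)
        for i in range(cfg.n_boundary_genes)
    ]

    # boundary genes sit at block left edges; drop any slot they would hit
    boundary_sites: list[tuple[str, str, int]] = []  # (label, chrom, edge)
    for label_needed in [p[0] for p in plan if p[2]]:
        cand = [b for b in blocks if b["label"] == label_needed and b["start"] > 0]
        cand = [
            b for b in cand
            if (b["chrom"], b["start"]) not in
            {(c, e) for _, c, e in boundary_sites}
        ]
        if not cand:
            raise SimulationError("no interior block available for boundary gene")
        b = cand[int(rng.integers(len(cand)))]
        boundary_sites.append((label_needed, b["chrom"], b["start"]))
    def hits_boundary_gene(chrom: str, pos: int) -> bool:
        return any(
            c == chrom
            and edge - _GENE_MARGIN <= pos < edge + _MAX_GENE_LEN + 2 * _GENE_MARGIN
            for _, c, edge in boundary_sites
        )

    for label in slots:
        slots[label] = [
            s for s in slots[label] if not hits_boundary_gene(*s)
        ]

    genes = []
    gene_truth = []
    boundary_iter = iter(boundary_sites)
    for idx, (label, crystallin, boundary) in enumerate(plan):
        gene_id = f"gene{idx:04d}"
        tx_id = f"{gene_id}.1"
        length = int(rng.integers(5_000, _MAX_GENE_LEN))
        if boundary:
            # + strand TSS 500 bp into the block: the 2 kb-up/500-down
            # promoter straddles the block's left edge with its larger
            # half in the neighbouring block
            _, chrom, edge = next(boundary_iter)
            tx_start = edge + 500
            strand = "+"
        else:
            if not slots[label]:
                raise SimulationError(
                    f"gene capacity exhausted for compartment {label} "
                    f"(category counts unsatisfiable on this genome)"
                )
            chrom, tx_start = slots[label].pop()
            strand = "+" if rng.random() < 0.5 else "-"
        tx_end = tx_start + length
        coding = not (rng.random() < cfg.frac_noncoding) or crystallin
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.integers(200, length - 200, size=2 * (n_exons - 1)))
        bounds = [0, *map(int, cuts), length]
        exons = tuple(
            (tx_start + bounds[2 * i], tx_start + bounds[2 * i + 1])
            for i in range(n_exons)
        )
        exons = tuple((s, e) for s, e in exons if e > s)
        if not exons or exons[0][0] != tx_start or exons[-1][1] != tx_end:
            # first exon must start and last exon end at the tx ends
            exons = ((tx_start, tx_end),)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=tx_id,
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exons=exons,
                coding=coding,
            )
        )
        if crystallin:
            x_epi = rng.normal(cfg.expr_log2_crystallin - 3, cfg.expr_log2_sd)
            x_fib = rng.normal(cfg.expr_log2_crystallin, cfg.expr_log2_sd)
        else:
            mean = cfg.expr_log2_mean_A if label == "A" else cfg.expr_log2_mean_B
            x_epi = rng.normal(mean, cfg.expr_log2_sd)
            x_fib = rng.normal(mean, cfg.expr_log2_sd)
        gene_truth.append(
            {
                "gene_id": gene_id,
                "transcript_id": tx_id,
                "chrom": chrom,
                "tx_start": tx_start,
                "tx_end": tx_end,
                "strand": strand,
                "label": label,
                "coding": coding,
                "crystallin": crystallin,
                "boundary": boundary,
                "fpkm": {
                    "epi": float(np.round(2.0 ** x_epi, 6)),
                    "fib": float(np.round(2.0 ** x_fib, 6)),
                },
            }
        )
    return genes, gene_truth


def _write_bed12(path, genes) -> None:
    rows = sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.transcript_id))
    with open(path, "w") as fh:
        for g in rows:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons) + ","
            thick = (g.tx_start, g.tx_end) if g.coding else (g.tx_start, g.tx_start)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        f"{g.gene_id}|{g.transcript_id}",
                        "0",
                        g.strand,
                        str(thick[0]),
                        str(thick[1]),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def _write_methylation(
    cfg: SimConfig, path, centers_by_chrom: dict[str, list[int]]
) -> None:
    """Constant-baseline methylation on the CpG grid with linear dips at
    peak centers; overlapping dips take the deeper (minimum) value."""
    with open(path, "w") as fh:
        for chrom in sorted(cfg.chrom_sizes):
            size = cfg.chrom_sizes[chrom]
            grid = np.arange(0, size - 2, cfg.cpg_spacing, dtype=np.int64)
            values = np.full(len(grid), cfg.meth_baseline)
            for center in centers_by_chrom.get(chrom, ()):
                lo = np.searchsorted(grid, center - cfg.meth_dip_halfwidth)
                hi = np.searchsorted(grid, center + cfg.meth_dip_halfwidth, "right")
                local = grid[lo:hi]
                dip = cfg.meth_baseline - cfg.meth_dip_depth * (
                    1 - np.abs(local - center) / cfg.meth_dip_halfwidth
                )
                values[lo:hi] = np.minimum(values[lo:hi], dip)
            np.savetxt(
                fh,
                np.column_stack([grid, grid + 2, values]),
                fmt=(f"{chrom}\t%d", "%d", "%.4f"),
                delimiter="\t",
            )
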