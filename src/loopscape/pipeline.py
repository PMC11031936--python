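"""Configuration-driven orchestration of all analysis stages.

A YAML config names the input files per cell type, toggles stages and sets
parameters; :func:`run` executes the enabled stages in dependency order,
writes one TSV per output table (each with a provenance comment line) and
returns a :class:`Report`. Stages are deterministic, so identical config
and inputs reproduce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .intervals import (
    TAD,
    aggregate_contact_stats,
    read_contact_stats,
    read_expression,
    read_genes_bed12,
    read_gmt,
    read_intervals,
    read_loops,
)
from .architecture import classify_loop, summarize, DEFAULT_LONG_LOOP_THRESHOLD
from .compartments import (
    assign_genes,
    expression_by_compartment,
    gene_consensus,
    read_pc_bedgraph,
)
from .ctcf import classify_loops_ctcf, classify_sharing, cross_analysis, metaprofile
from .enrichment import annotate_anchors, enrich, promoter_contact_genes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Report", "ConfigError", "validate_config", "run"]

STAGES = ("qc", "architecture", "compartments", "ctcf", "annotation", "enrichment")

_DEFAULT_PARAMS = {
    "long_threshold": DEFAULT_LONG_LOOP_THRESHOLD,
    "containment_mode": "midpoint",
    "promoter_upstream_compartments": 2000,
    "promoter_downstream_compartments": 500,
    "promoter_upstream_contacts": 2000,
    "promoter_downstream_contacts": 100,
    "flank": 5000,
    "bin_size": 100,
    "top_n": 100,
    "coding_only": True,
    "alpha": 0.05,
    "slack": 0,
    "rank_by": "fib",
}

_INPUT_KEYS = {
    "loops", "tads", "pc1", "ctcf_peaks", "ctcf_cov", "meth",
    "polii", "genes", "expression", "gmt", "contact_stats",
}
_PER_CELL_INPUTS = {"loops", "tads", "pc1", "ctcf_peaks", "ctcf_cov", "meth"}


class ConfigError(ValueError):
    """The pipeline config is malformed or references missing files."""


@dataclass
class PipelineConfig:
    inputs: dict
    params: dict
    stages: dict[str, bool]
    seed: int
    outdir: Path
    cells: list[str]

    def hash(self) -> str:
        blob = json.dumps(
            {
                "inputs": {k: _path_repr(v) for k, v in sorted(self.inputs.items())},
                "params": self.params,
                "stages": self.stages,
                "seed": self.seed,
                "cells": self.cells,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _path_repr(v):
    if isinstance(v, dict):
        return {k: str(p) for k, p in sorted(v.items())}
    return str(v)


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config.

    Unknown keys are rejected; referenced files must exist; defaults are
    filled in; stages with no configured inputs default to off.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {"inputs", "params", "stages", "seed", "outdir", "cells"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    inputs = raw.get("inputs", {}) or {}
    unknown_in = set(inputs) - _INPUT_KEYS
    if unknown_in:
        raise ConfigError(f"unknown input keys: {sorted(unknown_in)}")
    cells = list(raw.get("cells", ["epi", "fib"]))
    base = Path(path).parent
    resolved: dict = {}
    for key, value in inputs.items():
        if key in _PER_CELL_INPUTS:
            if not isinstance(value, dict):
                raise ConfigError(f"input {key!r} must map cell type -> path")
            resolved[key] = {}
            for cell, p in value.items():
                p = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
                if not p.exists():
                    raise ConfigError(f"input file for {key}/{cell} not found: {p}")
                resolved[key][cell] = p
        else:
            p = (base / value).resolve() if not Path(value).is_absolute() else Path(value)
            if not p.exists():
                raise ConfigError(f"input file for {key} not found: {p}")
            resolved[key] = p
    params = dict(_DEFAULT_PARAMS)
    user_params = raw.get("params", {}) or {}
    unknown_p = set(user_params) - set(params)
    if unknown_p:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown_p)}")
    params.update(user_params)

    auto = {
        "qc": "contact_stats" in resolved,
        "architecture": {"loops", "tads"} <= set(resolved),
        "compartments": {"pc1", "genes", "expression"} <= set(resolved),
        "ctcf": {"loops", "ctcf_peaks"} <= set(resolved),
        "annotation": {"loops", "genes"} <= set(resolved),
        "enrichment": {"loops", "genes", "gmt"} <= set(resolved),
    }
    stages = dict(auto)
    user_stages = raw.get("stages", {}) or {}
    unknown_s = set(user_stages) - set(STAGES)
    if unknown_s:
        raise ConfigError(f"unknown stage names: {sorted(unknown_s)}")
    stages.update({k: bool(v) for k, v in user_stages.items()})

    outdir = Path(raw.get("outdir", "loopscape_out"))
    if not outdir.is_absolute():
        outdir = base / outdir
    return PipelineConfig(
        inputs=resolved,
        params=params,
        stages=stages,
        seed=int(raw.get("seed", 0)),
        outdir=outdir,
        cells=cells,
    )


@dataclass
class Report:
    version: str
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failed

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages": self.stages,
                    "warnings": self.warnings,
                    "failed": self.failed,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


def _write_table(df: pd.DataFrame, path: Path, report: Report) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# loopscape v{report.version} config={report.config_hash} "
            f"seed={report.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run(config: PipelineConfig) -> Report:
    """Execute all enabled stages; a stage failure is recorded in the report
    (partial outputs are retained) and reflected in the CLI exit status."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    report = Report(version=__version__, config_hash=config.hash(), seed=config.seed)
    p = config.params

    loaded: dict = {}

    def load_loops(cell):
        if ("loops", cell) not in loaded:
            res = read_loops(config.inputs["loops"][cell])
            report.warnings.extend(res.warnings)
            loaded[("loops", cell)] = res.loops
        return loaded[("loops", cell)]

    def load_genes():
        if "genes" not in loaded:
            loaded["genes"] = read_genes_bed12(config.inputs["genes"])
        return loaded["genes"]

    for stage in STAGES:
        if not config.stages.get(stage):
            report.stages[stage] = {"status": "skipped"}
            continue
        try:
            if stage == "qc":
                stats = read_contact_stats(config.inputs["contact_stats"])
                summary = aggregate_contact_stats(stats)
                _write_table(
                    pd.DataFrame(
                        {
                            "n_samples": [summary.n_samples],
                            "total_contacts": [summary.total_contacts],
                            "total_millions": [summary.total_millions],
                            "total_billions": [summary.total_billions],
                        }
                    ),
                    config.outdir / "qc_contacts.tsv",
                    report,
                )
                report.stages[stage] = {
                    "status": "ok",
                    "total_contacts": summary.total_contacts,
                    "total_billions": summary.total_billions,
                }
            elif stage == "architecture":
                out: dict = {"status": "ok"}
                for cell in config.cells:
                    loops = load_loops(cell)
                    tads = [
                        TAD(iv)
                        for iv in read_intervals(
                            config.inputs["tads"][cell], format="bed3"
                        )
                    ]
                    summary = summarize(loops, tads, p["long_threshold"])
                    _write_table(
                        summary.to_frame(),
                        config.outdir / f"architecture_summary_{cell}.tsv",
                        report,
                    )
                    _write_table(
                        summary.per_chromosome,
                        config.outdir / f"architecture_per_chrom_{cell}.tsv",
                        report,
                    )
                    cats = [
                        classify_loop(lp, tads, p["containment_mode"]).value
                        for lp in loops
                    ]
                    cat_df = pd.DataFrame(
                        {
                            "loop_index": range(len(loops)),
                            "chrom": [lp.chrom for lp in loops],
                            "size": [lp.size for lp in loops],
                            "category": cats,
                        }
                    )
                    _write_table(
                        cat_df,
                        config.outdir / f"loop_categories_{cell}.tsv",
                        report,
                    )
                    counts = cat_df["category"].value_counts().to_dict()
                    out[cell] = {
                        "n_loops": summary.n_loops,
                        "n_tads": summary.n_tads,
                        "mean_loop_size": summary.mean_loop_size,
                        "median_loop_size": summary.median_loop_size,
                        "median_tad_size": summary.median_tad_size,
                        "n_long_loops": summary.n_long_loops,
                        "category_counts": {
                            c: int(counts.get(c, 0))
                            for c in ("intra", "inter", "one_anchor", "not_in_tad")
                        },
                    }
                report.stages[stage] = out
            elif stage == "compartments":
                out = {"status": "ok"}
                genes = load_genes()
                expr = read_expression(config.inputs["expression"])
                for cell in config.cells:
                    bins = read_pc_bedgraph(config.inputs["pc1"][cell])
                    calls = assign_genes(
                        genes,
                        bins,
                        p["promoter_upstream_compartments"],
                        p["promoter_downstream_compartments"],
                    )
                    consensus = gene_consensus(calls, genes)
                    call_df = pd.DataFrame(
                        {
                            "gene_id": [c.gene_id for c in calls],
                            "transcript_id": [c.transcript_id for c in calls],
                            "label": [c.label for c in calls],
                            "overlap_bp": [c.overlap_bp for c in calls],
                        }
                    )
                    _write_table(
                        call_df,
                        config.outdir / f"gene_compartments_{cell}.tsv",
                        report,
                    )
                    if cell in expr.columns:
                        ebc = expression_by_compartment(consensus, expr[cell])
                        report.warnings.extend(
                            [f"{cell}: {ebc.n_missing_expression} genes lack expression"]
                            if ebc.n_missing_expression
                            else []
                        )
                        _write_table(
                            ebc.to_frame(),
                            config.outdir / f"expression_by_compartment_{cell}.tsv",
                            report,
                        )
                        out[cell] = {
                            "n_calls": len(calls),
                            "median_log2_A": ebc.medians.get("A"),
                            "median_log2_B": ebc.medians.get("B"),
                        }
                report.stages[stage] = out
            elif stage == "ctcf":
                out = {"status": "ok"}
                peaks = {
                    cell: read_intervals(
                        config.inputs["ctcf_peaks"][cell], format="narrowPeak"
                    )
                    for cell in config.cells
                }
                if len(config.cells) == 2:
                    c1, c2 = config.cells
                    sharing, labeled = classify_sharing(peaks[c1], peaks[c2])
                    _write_table(
                        pd.DataFrame(
                            {
                                "n_set1": [sharing.n_set1],
                                "n_set2": [sharing.n_set2],
                                "n_shared": [sharing.n_shared],
                                "n_specific1": [sharing.n_specific1],
                                "n_specific2": [sharing.n_specific2],
                                "union": [sharing.union],
                                "percent_shared": [sharing.percent_shared],
                            }
                        ),
                        config.outdir / "ctcf_sharing.tsv",
                        report,
                    )
                    out["sharing"] = {
                        "n_shared": sharing.n_shared,
                        "n_specific1": sharing.n_specific1,
                        "n_specific2": sharing.n_specific2,
                        "percent_shared": sharing.percent_shared,
                    }
                for cell in config.cells:
                    counts, props = classify_loops_ctcf(
                        load_loops(cell), peaks[cell], p["slack"]
                    )
                    _write_table(
                        pd.DataFrame(
                            {
                                "n_bound_anchors": [0, 1, 2],
                                "n_loops": [counts[k] for k in (0, 1, 2)],
                                "proportion": [props[k] for k in (0, 1, 2)],
                            }
                        ),
                        config.outdir / f"ctcf_anchor_classes_{cell}.tsv",
                        report,
                    )
                    out[cell] = {"anchor_class_counts": counts}
                    if "meth" in config.inputs and cell in config.inputs["meth"]:
                        track = read_intervals(
                            config.inputs["meth"][cell], format="bedGraph"
                        )
                        profile = metaprofile(
                            peaks[cell], track, p["flank"], p["bin_size"]
                        )
                        _write_table(
                            profile.to_frame(),
                            config.outdir / f"meth_metaprofile_{cell}.tsv",
                            report,
                        )
                        out[cell]["meth_center_mean"] = float(
                            profile.mean_value[profile.center_index]
                        )
                if (
                    "ctcf_cov" in config.inputs
                    and "polii" in config.inputs
                    and "expression" in config.inputs
                    and "genes" in config.inputs
                ):
                    expr = read_expression(config.inputs["expression"])
                    tracks = {
                        cell: read_intervals(path, format="bedGraph")
                        for cell, path in config.inputs["ctcf_cov"].items()
                    }
                    polii = read_intervals(config.inputs["polii"], format="bedGraph")
                    xa, warns = cross_analysis(
                        expr,
                        load_genes(),
                        tracks,
                        polii,
                        rank_by=p["rank_by"],
                        top_n=p["top_n"],
                        coding_only=p["coding_only"],
                    )
                    report.warnings.extend(warns)
                    _write_table(
                        xa, config.outdir / "cross_analysis.tsv", report
                    )
                    out["cross_analysis_rows"] = int(len(xa))
                report.stages[stage] = out
            elif stage == "annotation":
                out = {"status": "ok"}
                genes = load_genes()
                contact_sets = {}
                for cell in config.cells:
                    loops = load_loops(cell)
                    ann_df, props = annotate_anchors(
                        loops,
                        genes,
                        p["promoter_upstream_contacts"],
                        p["promoter_downstream_contacts"],
                    )
                    _write_table(
                        ann_df,
                        config.outdir / f"anchor_annotation_{cell}.tsv",
                        report,
                    )
                    contacts = promoter_contact_genes(
                        loops,
                        genes,
                        p["promoter_upstream_contacts"],
                        p["promoter_downstream_contacts"],
                    )
                    contact_sets[cell] = contacts
                    _write_table(
                        pd.DataFrame({"gene_id": sorted(contacts)}),
                        config.outdir / f"promoter_contacts_{cell}.tsv",
                        report,
                    )
                    out[cell] = {
                        "annotation_proportions": props,
                        "n_promoter_contact_genes": len(contacts),
                    }
                if len(contact_sets) == 2:
                    names = sorted(contact_sets)
                    shared = contact_sets[names[0]] & contact_sets[names[1]]
                    out["shared_promoter_contacts"] = len(shared)
                loaded["contact_sets"] = contact_sets
                report.stages[stage] = out
            elif stage == "enrichment":
                out = {"status": "ok"}
                genes = load_genes()
                gmt = read_gmt(config.inputs["gmt"])
                universe = {g.gene_id for g in genes}
                contact_sets = loaded.get("contact_sets")
                if contact_sets is None:
                    contact_sets = {
                        cell: promoter_contact_genes(
                            load_loops(cell),
                            genes,
                            p["promoter_upstream_contacts"],
                            p["promoter_downstream_contacts"],
                        )
                        for cell in config.cells
                    }
                for cell, query in sorted(contact_sets.items()):
                    results = enrich(query, gmt, universe)
                    _write_table(
                        pd.DataFrame(
                            {
                                "term_id": [r.term_id for r in results],
                                "k": [r.k for r in results],
                                "K": [r.K for r in results],
                                "n": [r.n for r in results],
                                "N": [r.N for r in results],
                                "p": [r.p for r in results],
                                "q": [r.q for r in results],
                            }
                        ),
                        config.outdir / f"enrichment_{cell}.tsv",
                        report,
                    )
                    out[cell] = {
                        "n_terms_tested": len(results),
                        "n_significant_q05": sum(1 for r in results if r.q < 0.05),
                    }
                report.stages[stage] = out
        except Exception as exc:  # noqa: BLE001 - stage isolation by contract
            logger.exception("stage %s failed", stage)
            report.stages[stage] = {"status": "failed", "error": str(exc)}
            report.failed.append(stage)

    report.to_json(config.outdir / "report.json")
    return report
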