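"""End-to-end orchestration: simulate/load -> filter -> align -> evaluate -> report.

The pipeline is a thin composition of the library stages with a single
config object, deterministic seeding, stderr logging, and publication-
style report tables.  Re-running with an identical config reproduces
byte-identical TSV outputs; every run directory carries a provenance JSON
naming inputs, thresholds, seed and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotations import GeneRecord, read_clusters, read_gff3
from .assembly_metrics import (
    AssemblyReport,
    CLASS_BOUNDS,
    MISARRANGEMENT_MIN_SIZE,
    MISJOIN_DISTANCE_BOUND,
    SCAFFOLD_SIZE_FLOOR,
    classify_misarrangements,
    evaluate_assembly,
)
from .colorspace import pair_reads, read_color_reads, write_color_reads
from .fragment_align import (
    DEFAULT_MIN_SCORE,
    align_scaffolds,
    load_fragments,
)
from .gene_reconstruction import (
    EVALUE_MAX,
    cluster_continuity,
    evaluate_genes,
    summarize_genes,
)
from .read_filter import FilterPolicy, FilterStats, filter_pairs
from .seqio import read_fasta

logger = logging.getLogger("asmrecon")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""


@dataclass
class RunConfig:
    """One assessment run: input paths, thresholds, seed, output directory."""

    reference: str | None = None
    scaffolds: str | None = None
    reads_csfasta: str | None = None
    reads_qual: str | None = None
    alignments: str | None = None  # precomputed PAF; else built-in aligner
    annotations: str | None = None  # GFF3 gene rows
    clusters: str | None = None  # YAML ordered gene lists

    name: str = "assembly"
    filter_mode: str = "nofilter"
    qv_threshold: int = 10
    pair_rule: str = "both_pass"
    min_score: int = DEFAULT_MIN_SCORE
    misarrangement_min_size: int = MISARRANGEMENT_MIN_SIZE
    misjoin_bound: int = MISJOIN_DISTANCE_BOUND
    class_bounds: tuple[int, int] = CLASS_BOUNDS
    size_floor: int = SCAFFOLD_SIZE_FLOOR
    evalue_max: float = EVALUE_MAX
    seed: int = 0
    outdir: str = "asmrecon_out"

    def __post_init__(self) -> None:
        for attr in ("misarrangement_min_size", "misjoin_bound", "size_floor"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "class_bounds" in data:
            data["class_bounds"] = tuple(data["class_bounds"])
        return cls(**data)


@dataclass
class PipelineResult:
    report: AssemblyReport
    events: list
    gene_results: dict = field(default_factory=dict)
    gene_summary: dict = field(default_factory=dict)
    cluster_table: pd.DataFrame | None = None
    filter_stats: FilterStats | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise PipelineError(f"config is missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"{what} path does not exist: {p}")
    return p


@_stage("filter")
def _run_filter(config: RunConfig, outdir: Path) -> FilterStats:
    cs = _require(config.reads_csfasta, "reads_csfasta")
    qu = _require(config.reads_qual, "reads_qual")
    policy = FilterPolicy(config.filter_mode, config.qv_threshold, config.pair_rule)
    pairs, orphans = pair_reads(read_color_reads(cs, qu))
    stats = FilterStats(orphans=len(orphans))
    survivors = list(filter_pairs(pairs, policy, stats))
    flat = [r for pair in survivors for r in pair]
    write_color_reads(flat, outdir / "filtered.csfasta", outdir / "filtered.qual")
    pd.DataFrame([stats.as_dict()]).to_csv(
        outdir / "filter_stats.tsv", sep="\t", index=False
    )
    return stats


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all configured stages in order and write the report tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    reference = read_fasta(_require(config.reference, "reference"))
    scaffolds = read_fasta(_require(config.scaffolds, "scaffolds"))

    filter_stats = None
    if config.reads_csfasta:
        filter_stats = _run_filter(config, outdir)

    if config.alignments:
        fragments = load_fragments(
            _require(config.alignments, "alignments"), config.min_score
        )
    else:
        fragments = _stage("align")(align_scaffolds)(
            scaffolds, reference, min_score=config.min_score
        )

    genes: list[GeneRecord] = []
    gene_intervals = None
    if config.annotations:
        genes = read_gff3(_require(config.annotations, "annotations"))
        gene_intervals = {}
        for g in genes:
            gene_intervals.setdefault(g.chrom, []).append((g.start, g.end))

    report = _stage("evaluate")(evaluate_assembly)(
        config.name,
        scaffolds,
        reference,
        fragments,
        gene_intervals=gene_intervals,
        min_size=config.misarrangement_min_size,
        misjoin_bound=config.misjoin_bound,
    )
    events = classify_misarrangements(
        fragments, config.misarrangement_min_size, config.misjoin_bound
    )

    gene_results: dict = {}
    gene_summary: dict = {}
    cluster_table = None
    if genes:
        gene_results = _stage("genes")(evaluate_genes)(
            genes, reference, scaffolds, config.evalue_max, config.size_floor
        )
        gene_summary = summarize_genes(gene_results)
        smb = [
            g.gene_id
            for g in genes
            if "polyketide" in g.product or "non-ribosomal" in g.product
        ]
        if smb:
            sub = summarize_genes(gene_results, subset=smb)
            gene_summary["pks_nrps_hsp_pct"] = sub["hsp_pct"]
            gene_summary["pks_nrps_identity_pct"] = sub["identity_pct"]
        if config.clusters:
            clusters = read_clusters(_require(config.clusters, "clusters"))
            cluster_table = pd.DataFrame(
                [
                    dict(
                        cluster=name,
                        n_genes=len(ids),
                        continuous=cluster_continuity(ids, gene_results),
                    )
                    for name, ids in clusters.items()
                ]
            )

    outputs = _write_outputs(
        config, outdir, report, events, gene_results, gene_summary, cluster_table
    )
    return PipelineResult(
        report=report,
        events=events,
        gene_results=gene_results,
        gene_summary=gene_summary,
        cluster_table=cluster_table,
        filter_stats=filter_stats,
        outputs=outputs,
    )


def _write_outputs(
    config, outdir, report, events, gene_results, gene_summary, cluster_table
) -> dict[str, Path]:
    outputs: dict[str, Path] = {}
    for style in ("table2", "table4", "table5", "table6"):
        df = render_report([report], style)
        p = outdir / f"report_{style}.tsv"
        df.to_csv(p, sep="\t", index=False)
        outputs[style] = p
    ev = pd.DataFrame(
        [dataclasses.asdict(e) for e in events],
        columns=["kind", "scaffold_id", "ref_chrom", "ref_pos", "size", "scaffold_pos"],
    )
    outputs["events"] = outdir / "events.tsv"
    ev.to_csv(outputs["events"], sep="\t", index=False)
    if gene_results:
        gr = pd.DataFrame(
            [
                dict(
                    gene_id=r.gene_id,
                    length=r.gene_length,
                    best_scaffold=r.best_scaffold or "",
                    hsp_fraction=round(r.hsp_fraction, 6),
                    identity_fraction=round(r.identity_fraction, 6),
                    lost=r.lost,
                )
                for r in gene_results.values()
            ]
        )
        outputs["genes"] = outdir / "genes.tsv"
        gr.to_csv(outputs["genes"], sep="\t", index=False)
    if cluster_table is not None:
        outputs["clusters"] = outdir / "clusters.tsv"
        cluster_table.to_csv(outputs["clusters"], sep="\t", index=False)
    prov = {
        "tool": "asmrecon",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "gene_summary": {k: round(v, 6) for k, v in gene_summary.items()},
    }
    outputs["provenance"] = outdir / "provenance.json"
    with open(outputs["provenance"], "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outputs


# ---------------------------------------------------------------------------
# Publication-style report tables
# ---------------------------------------------------------------------------

_STYLE_COLUMNS = {
    "table2": [
        "Name", "Depth (x)", "Number (>95 bp)", "Number (>500 bp)", "N50 (kb)",
        "Max (kb)", "Coverage (%)", "R50 (bp)", "Contig number (>95 bp)",
        "Contig N50 (kb)",
    ],
    "table4": [
        "Assembly", "Misjoin", "Inversion", "Deletion", "Insertion",
        "Deletion size (kb)", "Insertion size (kb)",
    ],
    "table5": [
        "Assembly", "Genome insertion", "Genome deletion",
        "Gene insertion", "Gene deletion",
    ],
    "table6": ["Assembly", "Contig", "Scaffold", "Contig/scaffold"],
}


def render_report(
    reports: Sequence[AssemblyReport], style: str
) -> pd.DataFrame:
    """Render reports as a publication-style table (one row per assembly).

    Formatting: kb columns 0 decimals, coverage 2 decimals, ratio 2
    decimals.  An empty report list yields a header-only table.
    """
    if style not in _STYLE_COLUMNS:
        raise ValueError(f"unknown report style {style!r}")
    cols = _STYLE_COLUMNS[style]
    rows = []
    for r in reports:
        if style == "table2":
            rows.append(
                [
                    r.name,
                    f"{r.depth:.0f}",
                    r.scaffold_stats.n_scaffolds_95,
                    r.scaffold_stats.n_scaffolds_500,
                    f"{r.scaffold_stats.n50 / 1000:.0f}",
                    f"{r.scaffold_stats.max / 1000:.0f}",
                    f"{r.coverage_pct:.2f}",
                    r.r50,
                    r.n_contigs,
                    f"{r.contig_n50 / 1000:.0f}",
                ]
            )
        elif style == "table4":
            m = r.misarrangements
            rows.append(
                [
                    r.name, m.get("misjoin", 0), m.get("inversion", 0),
                    m.get("deletion", 0), m.get("insertion", 0),
                    f"{r.deletion_total_bp / 1000:.0f}",
                    f"{r.insertion_total_bp / 1000:.0f}",
                ]
            )
        elif style == "table5":
            rows.append(
                [
                    r.name, r.small_indels_genome[0], r.small_indels_genome[1],
                    r.small_indels_gene[0], r.small_indels_gene[1],
                ]
            )
        else:
            rows.append(
                [r.name, r.n_contigs, r.scaffold_stats.n_scaffolds_95,
                 f"{r.scaffolding_ratio:.2f}"]
            )
    return pd.DataFrame(rows, columns=cols)
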