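"""End-to-end orchestration: scan -> associate -> filter -> network -> disease.

One :class:`PipelineConfig` (plain YAML mapping, CLI flags take
precedence) drives all stages.  Each stage writes its outputs before the
next begins; stages whose inputs are absent are skipped and marked so in
the run manifest.  The manifest records a config snapshot, input
checksums, per-stage record counts (the analysis' headline numbers), the
package version and timestamps; re-running on identical inputs
reproduces identical counts and byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import io as pio
from .motif_scan import DEFAULT_MOTIF, IUPACPattern, read_fasta, scan_genome
from .gene_association import (
    AssociationWindow,
    associate_genes,
    filter_gene_set,
    read_annotation,
)
from .network_analysis import hub_genes, load_scored_network, neighborhood
from .disease_annotation import filter_gda, pivot_matrix, read_gda

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated inputs and parameters for one pipeline run."""

    out_dir: str
    fasta: list[str] = field(default_factory=list)
    motif: str = DEFAULT_MOTIF
    strands: str = "both"
    overlapping: bool = True
    genome_ambiguity: str = "strict"
    respect_softmask: bool = False
    annotation: Optional[str] = None
    annotation_format: str = "BED"
    gene_set: Optional[str] = None
    upstream_bp: int = 10_000
    downstream_bp: int = 20_000
    orientation_mode: str = "site-strand"
    edges: Optional[str] = None
    edge_dialect: str = "simple-tsv"
    min_confidence: float = 0.7
    top_k: int = 10
    measures: tuple[str, ...] = ("degree", "closeness", "betweenness")
    hub_candidates: str = "all"          # or "query-only"
    gda: Optional[str] = None
    gda_min_score: float = 0.3
    gda_excluded_types: tuple[str, ...] = ("phenotype",)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["measures"] = list(self.measures)
        d["gda_excluded_types"] = list(self.gda_excluded_types)
        return d

    def validate(self) -> None:
        for p in list(self.fasta) + [
            p for p in (self.annotation, self.gene_set, self.edges, self.gda)
            if p
        ]:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValueError("min_confidence must lie in [0, 1]")
        if not (0.0 <= self.gda_min_score <= 1.0):
            raise ValueError("gda_min_score must lie in [0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")
        if self.hub_candidates not in ("all", "query-only"):
            raise ValueError(f"unknown hub_candidates {self.hub_candidates!r}")


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: dict[str, str] = field(default_factory=dict)   # run | skipped | failed
    counts: dict[str, object] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _log(quiet: bool, stage: str, msg: str) -> None:
    if not quiet:
        print(f"[ppre:{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, quiet: bool = False) -> RunManifest:
    """Execute all configured stages in order; returns the run manifest.

    A stage failure aborts the run with the stage name attached; outputs
    written up to that point are retained and the manifest (written on
    success and failure alike) marks the failed stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    for p in list(config.fasta) + [
        p for p in (config.annotation, config.gene_set, config.edges, config.gda) if p
    ]:
        manifest.input_checksums[str(p)] = _sha256(p)

    stage = "scan"
    try:
        sites = []
        if config.fasta:
            pattern = IUPACPattern(config.motif)

            def genome():
                for path in config.fasta:
                    yield from read_fasta(path)

            sites, summary = scan_genome(
                pattern, genome(), config.strands,
                genome_ambiguity=config.genome_ambiguity,
                respect_softmask=config.respect_softmask,
                overlapping=config.overlapping,
            )
            pio.write_sites_bed(sites, out / "sites.bed")
            pio.write_sites_tsv(sites, out / "sites.tsv")
            pio.write_summary(summary, out / "scan_summary.tsv",
                              out / "scan_summary.json")
            manifest.stages[stage] = "run"
            manifest.counts["sites_total"] = summary.total_sites
            manifest.counts["sites_positive"] = summary.positive_count
            manifest.counts["sites_negative"] = summary.negative_count
            _log(quiet, stage, f"{summary.total_sites} sites "
                 f"({summary.positive_count}+ / {summary.negative_count}-)")
        else:
            manifest.stages[stage] = "skipped"

        stage = "associate"
        associated_symbols: set[str] = set()
        if config.annotation and sites:
            genes = read_annotation(config.annotation, config.annotation_format)
            window = AssociationWindow(config.upstream_bp, config.downstream_bp,
                                       config.orientation_mode)
            pairs, summary2 = associate_genes(
                sites, genes, window,
                warn=lambda m: _log(quiet, "associate", "warning: " + m),
            )
            pio.write_associations(pairs, out / "associations.tsv")
            for strand, syms in sorted(summary2.genes_by_site_strand.items()):
                name = "plus" if strand == "+" else "minus"
                (out / f"genes_site_strand_{name}.txt").write_text(
                    "\n".join(sorted(syms)) + ("\n" if syms else "")
                )
            associated_symbols = set().union(
                *summary2.genes_by_site_strand.values()
            ) if summary2.genes_by_site_strand else set()
            (out / "genes_all.txt").write_text(
                "\n".join(sorted(associated_symbols))
                + ("\n" if associated_symbols else "")
            )
            manifest.stages[stage] = "run"
            manifest.counts["association_pairs"] = len(pairs)
            manifest.counts["associated_genes_total"] = summary2.total_unique_genes
            manifest.counts["associated_genes_by_site_strand"] = {
                s: len(v) for s, v in sorted(summary2.genes_by_site_strand.items())
            }
            _log(quiet, stage, f"{summary2.total_unique_genes} unique genes "
                 f"from {len(pairs)} site-gene pairs")
        else:
            manifest.stages[stage] = "skipped"

        stage = "filter-set"
        filtered: set[str] = set()
        if config.gene_set and associated_symbols:
            reference = {
                line.strip() for line in open(config.gene_set)
                if line.strip()
            }
            filtered = filter_gene_set(associated_symbols, reference)
            (out / "filtered_genes.txt").write_text(
                "\n".join(sorted(filtered)) + ("\n" if filtered else "")
            )
            manifest.stages[stage] = "run"
            manifest.counts["filtered_set_size"] = len(filtered)
            _log(quiet, stage, f"{len(filtered)} genes in reference set")
        else:
            manifest.stages[stage] = "skipped"

        stage = "network"
        if config.edges and filtered:
            network = load_scored_network(
                config.edges, dialect=config.edge_dialect,
                min_confidence=config.min_confidence,
            )
            queries = sorted(s.upper() for s in filtered)
            sub, report = neighborhood(network, queries)
            pio.write_edge_list(sub, out / "neighborhood_edges.tsv")
            pio.write_neighborhood_report(report, out / "neighborhood_report.tsv")
            hubs = hub_genes(
                sub, top_k=config.top_k, measures=config.measures,
                candidates=queries if config.hub_candidates == "query-only" else None,
                warn=lambda m: _log(quiet, "network", "warning: " + m),
            )
            pio.write_hub_report(hubs, out / "hub_report.tsv", out / "hub_report.json")
            manifest.stages[stage] = "run"
            manifest.counts["per_query_interactors"] = dict(
                sorted(report.per_query_counts.items())
            )
            manifest.counts["interactor_union"] = report.total_interactors
            manifest.counts["interactor_union_with_queries"] = (
                report.total_interactors_with_queries
            )
            manifest.counts["coverage_percent"] = report.coverage_percent
            manifest.counts["hub_union_size"] = len(hubs.union_set)
            manifest.counts["hub_intersection_size"] = len(hubs.intersection_set)
            manifest.counts["hub_union"] = sorted(hubs.union_set)
            manifest.counts["hub_intersection"] = sorted(hubs.intersection_set)
            _log(quiet, stage, f"{report.total_interactors} interactors, "
                 f"coverage {report.coverage_percent}%, hubs "
                 f"{len(hubs.union_set)}U/{len(hubs.intersection_set)}I")
        else:
            manifest.stages[stage] = "skipped"

        stage = "disease"
        if config.gda:
            records = read_gda(config.gda)
            kept = filter_gda(records, config.gda_min_score,
                              config.gda_excluded_types)
            with open(out / "gda_filtered.tsv", "w") as fh:
                fh.write("gene\tdisease_name\tdisease_type\tscore\n")
                for r in kept:
                    fh.write(f"{r.gene}\t{r.disease_name}\t{r.disease_type}"
                             f"\t{r.score}\n")
            matrix = pivot_matrix(kept)
            matrix.to_frame().to_csv(out / "gda_matrix.tsv", sep="\t")
            manifest.stages[stage] = "run"
            manifest.counts["gda_records"] = len(records)
            manifest.counts["gda_kept"] = len(kept)
            _log(quiet, stage, f"{len(kept)} of {len(records)} GDA records kept")
        else:
            manifest.stages[stage] = "skipped"
    except Exception as exc:
        manifest.stages[stage] = "failed"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return manifest
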