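"""Readers and writers for the pipeline's tabular interchange formats.

Site tables are emitted both as BED6 (0-based half-open, name column =
matched forward-strand sequence) and as a TSV that additionally carries
1-based inclusive coordinates for NCBI-style displays.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .motif_scan import GenomicSite, ScanSummary
from .gene_association import SiteGeneAssociation
from .network_analysis import HubReport, NeighborhoodReport

__all__ = [
    "write_sites_bed",
    "write_sites_tsv",
    "read_sites_bed",
    "write_summary",
    "write_associations",
    "write_neighborhood_report",
    "write_hub_report",
    "write_edge_list",
]


def write_sites_bed(sites: Iterable[GenomicSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.matched_seq}\t0\t{s.strand}\n")


def write_sites_tsv(sites: Iterable[GenomicSite], path) -> None:
    """TSV with both BED (0-based half-open) and 1-based inclusive columns."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart_0based\tend_0based\tstart_1based\tend_1based"
                 "\tstrand\tmatched_seq\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.start + 1}\t{s.end}"
                     f"\t{s.strand}\t{s.matched_seq}\n")


def read_sites_bed(path) -> list[GenomicSite]:
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                sites.append(GenomicSite(f[0], int(f[1]), int(f[2]),
                                         f[5], f[3]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED6 line: {exc}") from exc
    return sites


def write_summary(summary: ScanSummary, tsv_path, json_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("chrom\tpositive\tnegative\ttotal\n")
        for chrom, (p, n) in summary.per_chromosome_counts.items():
            fh.write(f"{chrom}\t{p}\t{n}\t{p + n}\n")
        fh.write(f"TOTAL\t{summary.positive_count}\t{summary.negative_count}"
                 f"\t{summary.total_sites}\n")
    with open(json_path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
        fh.write("\n")


def write_associations(pairs: Sequence[SiteGeneAssociation], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tsite_start\tsite_end\tsite_strand\tgene_symbol"
                 "\tgene_start\tgene_end\tgene_strand\trelation\tsigned_distance\n")
        for a in pairs:
            fh.write(f"{a.site.chrom}\t{a.site.start}\t{a.site.end}\t{a.site.strand}"
                     f"\t{a.gene.symbol}\t{a.gene.start}\t{a.gene.end}"
                     f"\t{a.gene.strand}\t{a.relation}\t{a.signed_distance}\n")


def write_neighborhood_report(report: NeighborhoodReport, path) -> None:
    """Table-1-style layout: one gene per row with its interactor count."""
    rows = sorted(report.per_query_counts.items(), key=lambda t: (-t[1], t[0]))
    with open(path, "w") as fh:
        fh.write("gene\tinteractor_count\n")
        for gene, count in rows:
            fh.write(f"{gene}\t{count}\n")
        fh.write(f"# total_interactors\t{report.total_interactors}\n")
        fh.write(f"# total_interactors_with_queries\t"
                 f"{report.total_interactors_with_queries}\n")
        fh.write(f"# coverage_percent\t{report.coverage_percent}\n")


def write_hub_report(report: HubReport, tsv_path, json_path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("measure\trank\tgene\tscore\n")
        for measure, ranking in report.rankings.items():
            for rank, (gene, score) in enumerate(ranking, 1):
                fh.write(f"{measure}\t{rank}\t{gene}\t{score}\n")
    with open(json_path, "w") as fh:
        json.dump(
            {
                "top_k": report.top_k,
                "rankings": {m: [[g, s] for g, s in r]
                             for m, r in report.rankings.items()},
                "union": sorted(report.union_set),
                "intersection": sorted(report.intersection_set),
            },
            fh, indent=2,
        )
        fh.write("\n")


def write_edge_list(graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol_a\tsymbol_b\tconfidence\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('confidence', '')}\n")
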