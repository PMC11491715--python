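"""Window-based assignment of genes to motif sites, and gene-set filtering.

Each response-element site defines an association window — by default
10 kb upstream and 20 kb downstream of the site in the site's own strand
orientation — and every gene whose body overlaps that window (half-open
interval intersection) is associated with the site.  Associated gene
symbols can then be intersected with a named reference set (here, the
human kinome) to extract the kinases under putative motif control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .motif_scan import GenomicSite

__all__ = [
    "GeneRecord",
    "AssociationWindow",
    "SiteGeneAssociation",
    "AssociatedGeneSummary",
    "read_annotation",
    "window_for_site",
    "associate_genes",
    "filter_gene_set",
]


@dataclass(frozen=True, order=True)
class GeneRecord:
    """An annotated gene interval, 0-based half-open, with a symbol."""

    chrom: str
    start: int
    end: int
    strand: str
    symbol: str
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid gene interval [{self.start}, {self.end}) for {self.symbol!r}"
            )
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class AssociationWindow:
    """Window geometry around a site.

    ``orientation_mode='site-strand'`` (default) applies upstream/downstream
    in the site's orientation, so for a minus-strand site upstream means
    larger coordinates.  ``'forward-fixed'`` always extends upstream_bp to
    the left and downstream_bp to the right in forward coordinates,
    mirroring a strand-agnostic table-browser query.
    """

    upstream_bp: int = 10_000
    downstream_bp: int = 20_000
    orientation_mode: str = "site-strand"

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window extents must be non-negative")
        if self.orientation_mode not in ("site-strand", "forward-fixed"):
            raise ValueError(
                f"unknown orientation_mode {self.orientation_mode!r}"
            )


@dataclass(frozen=True)
class SiteGeneAssociation:
    """One (site, gene) link with its relation and signed distance.

    ``signed_distance`` is 0 when the gene body overlaps the site itself;
    otherwise it is the 1-based offset of the nearest gene base from the
    site edge, positive downstream of the site in its orientation and
    negative upstream.
    """

    site: GenomicSite
    gene: GeneRecord
    signed_distance: int
    relation: str


@dataclass
class AssociatedGeneSummary:
    """Unique associated symbols grouped by site strand (and gene strand)."""

    genes_by_site_strand: dict[str, set[str]] = field(default_factory=dict)
    genes_by_gene_strand: dict[str, set[str]] = field(default_factory=dict)
    total_unique_genes: int = 0


def read_annotation(path, format: str = "BED", feature_filter: Optional[str] = "gene") -> list[GeneRecord]:
    """Read gene records from BED (0-based) or GFF3 (1-based, converted).

    BED uses columns chrom/start/end/name/score/strand; GFF3 rows are
    restricted to ``feature_filter`` (default ``gene``) and the symbol is
    taken from the ``gene_name``, ``Name`` or ``ID`` attribute, in that
    order.  Records are validated, sorted by (chrom, start), and exact
    duplicates collapsed.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"unknown annotation format {format!r}")
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if fmt == "BED":
                    if len(fields) < 4:
                        raise ValueError("fewer than 4 BED columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    symbol = fields[3]
                    strand = fields[5] if len(fields) > 5 else "."
                    records.append(GeneRecord(chrom, start, end, strand, symbol))
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 GFF3 columns")
                    if feature_filter and fields[2] != feature_filter:
                        continue
                    chrom = fields[0]
                    start = int(fields[3]) - 1  # GFF3 is 1-based inclusive
                    end = int(fields[4])
                    strand = fields[6] if fields[6] in ("+", "-") else "."
                    attrs = dict(
                        kv.split("=", 1)
                        for kv in fields[8].split(";")
                        if "=" in kv
                    )
                    symbol = attrs.get("gene_name") or attrs.get("Name") or attrs.get("ID")
                    if not symbol:
                        raise ValueError("no gene_name/Name/ID attribute")
                    records.append(GeneRecord(chrom, start, end, strand, symbol,
                                              source_id=attrs.get("ID")))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {fmt} line: {exc}") from exc
    uniq = sorted(set(records), key=lambda g: (g.chrom, g.start, g.end, g.symbol))
    return uniq


def window_for_site(
    site: GenomicSite,
    window: AssociationWindow,
    chrom_length: Optional[int] = None,
) -> tuple[int, int]:
    """Half-open window interval around a site, clamped to the chromosome."""
    if window.orientation_mode == "forward-fixed" or site.strand == "+":
        lo = site.start - window.upstream_bp
        hi = site.end + window.downstream_bp
    else:  # minus-strand site, site-strand mode: orientation mirrored
        lo = site.start - window.downstream_bp
        hi = site.end + window.upstream_bp
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def _relation(site: GenomicSite, gene: GeneRecord) -> tuple[int, str]:
    """Signed distance and relation label for an associated pair."""
    if gene.start < site.end and site.start < gene.end:
        return 0, "overlaps-site"
    if gene.start >= site.end:  # gene right of site in forward coordinates
        d = gene.start - site.end + 1
        right_is_downstream = site.strand != "-"
    else:  # gene left of site
        d = -(site.start - gene.end + 1)
        right_is_downstream = site.strand != "-"
    if not right_is_downstream:
        d = -d
    return (d, "downstream-window" if d > 0 else "upstream-window")


def associate_genes(
    sites: Sequence[GenomicSite],
    genes: Sequence[GeneRecord],
    window: AssociationWindow = AssociationWindow(),
    chrom_lengths: Optional[dict[str, int]] = None,
    *,
    method: str = "indexed",
    containment: bool = False,
    warn: Optional[callable] = None,
) -> tuple[list[SiteGeneAssociation], AssociatedGeneSummary]:
    """Associate every site with the genes overlapping its window.

    ``method='indexed'`` uses an interval tree per chromosome
    (sub-quadratic); ``method='brute-force'`` checks all pairs and exists
    as the testing oracle.  With ``containment`` a gene must lie entirely
    inside the window rather than merely overlap it.  Chromosomes that
    carry sites but no annotation yield zero associations (reported via
    ``warn`` when provided).
    """
    if method not in ("indexed", "brute-force"):
        raise ValueError(f"unknown association method {method!r}")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    trees: dict[str, IntervalTree] = {}
    if method == "indexed":
        for chrom, glist in by_chrom.items():
            trees[chrom] = IntervalTree.from_tuples(
                (g.start, g.end, g) for g in glist
            )
    pairs: list[SiteGeneAssociation] = []
    warned: set[str] = set()
    for site in sites:
        if site.chrom not in by_chrom:
            if warn is not None and site.chrom not in warned:
                warn(f"chromosome {site.chrom!r} has sites but no annotation")
                warned.add(site.chrom)
            continue
        lo, hi = window_for_site(
            site, window,
            chrom_lengths.get(site.chrom) if chrom_lengths else None,
        )
        if method == "indexed":
            hits = [iv.data for iv in trees[site.chrom].overlap(lo, hi)]
        else:
            hits = [g for g in by_chrom[site.chrom] if g.start < hi and lo < g.end]
        for gene in hits:
            if containment and not (lo <= gene.start and gene.end <= hi):
                continue
            d, rel = _relation(site, gene)
            pairs.append(SiteGeneAssociation(site, gene, d, rel))
    pairs.sort(key=lambda a: (a.site.chrom, a.site.start, a.site.strand,
                              a.gene.start, a.gene.end, a.gene.symbol))
    summary = AssociatedGeneSummary()
    all_symbols: set[str] = set()
    for a in pairs:
        summary.genes_by_site_strand.setdefault(a.site.strand, set()).add(a.gene.symbol)
        summary.genes_by_gene_strand.setdefault(a.gene.strand, set()).add(a.gene.symbol)
        all_symbols.add(a.gene.symbol)
    summary.total_unique_genes = len(all_symbols)
    return pairs, summary


def filter_gene_set(
    symbols: Iterable[str],
    reference_set: Iterable[str],
    case_fold: bool = True,
) -> set[str]:
    """Intersect ``symbols`` with a reference gene set.

    With ``case_fold`` the match is case-insensitive and the returned
    symbols carry the reference set's casing (the convention of curated
    gene lists).
    """
    ref = set(reference_set)
    if not case_fold:
        return set(symbols) & ref
    by_fold = {r.casefold(): r for r in ref}
    return {by_fold[s.casefold()] for s in symbols if s.casefold() in by_fold}
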