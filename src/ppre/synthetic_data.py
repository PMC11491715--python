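"""Seeded synthetic fixtures with machine-readable ground truth.

Every pipeline stage can be exercised without downloads: the generators
emit a genome FASTA with motif occurrences planted at known coordinates
and strands on a motif-scrubbed background, a BED annotation with genes
placed at controlled distances from the planted sites, a scored edge
list with known per-query interactor counts and a designated
high-centrality bridge node, a kinase-style gene-set list, and a
gene-disease table straddling the 0.3 score cutoff.  A single seed feeds
named sub-streams (genome / annotation / network / gda), so outputs are
byte-identical across runs and one stage can be regenerated without
perturbing the others.

Ground truth is derived by construction and validated at generation time
against naive oracles kept in this module (position-by-position motif
scan, all-pairs window overlap, adjacency recount), which are
independent of the package's production code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .motif_scan import (
    DEFAULT_MOTIF,
    IUPAC_SETS,
    IUPACPattern,
    GenomicSite,
    SequenceRecord,
    reverse_complement,
)
from .gene_association import AssociationWindow, GeneRecord
from .disease_annotation import GDARecord

__all__ = [
    "GenomeConfig",
    "AnnotationConfig",
    "NetworkConfig",
    "GDAConfig",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_annotation",
    "generate_network",
    "generate_gda",
    "write_fixture",
    "kinase_panel_config",
    "TABLE1_KINASES",
    "TABLE1_DEGREES",
    "naive_scan",
    "naive_associate",
]

# The 29 PPRE-associated kinase symbols and their reported high-confidence
# interactor counts, used by the kinase-panel preset to give the synthetic
# interactome the same query-degree spread as the real analysis.
TABLE1_KINASES = (
    "PRKDC", "HGS", "PRKCZ", "MET", "PTK2", "CLK2", "CDK8", "PRPF6",
    "MYLK2", "STK24", "TNK2", "CERK", "MAP3K6", "STK35", "SIK3", "PDK2",
    "MAGI2", "AKAP14", "CERKL", "KALRN", "PFKFB4", "PIK3CD", "PRKCH",
    "MAP3K15", "MOB3C", "SPEG", "FAM47E", "BRSK2", "SRRM5",
)
TABLE1_DEGREES = (
    167, 155, 128, 113, 94, 88, 81, 77, 77, 70, 42, 41, 21, 15, 14, 14,
    12, 10, 9, 7, 7, 6, 6, 5, 4, 4, 2, 1, 0,
)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class GenomeConfig:
    n_chromosomes: int = 1
    lengths: tuple[int, ...] = (100_000,)
    gc_fraction: float = 0.41          # human-like GC content
    n_planted_plus: int = 12
    n_planted_minus: int = 8
    scrub_background: bool = True


@dataclass(frozen=True)
class AnnotationConfig:
    n_genes_inside_window: int = 2
    n_genes_boundary: bool = True      # plant the one-base-in / first-base-out pair
    n_genes_outside: int = 1
    gene_length_range: tuple[int, int] = (500, 3_000)


@dataclass(frozen=True)
class NetworkConfig:
    n_background_nodes: int = 30
    background_edge_prob: float = 0.08
    per_query_planted_degrees: tuple[int, ...] = (5, 3, 0)
    n_low_confidence_per_query: int = 2   # sub-threshold edges, must be dropped
    high_score_range: tuple[float, float] = (0.70, 0.99)
    low_score_range: tuple[float, float] = (0.30, 0.699)
    background_score_range: tuple[float, float] = (0.40, 0.99)


@dataclass(frozen=True)
class GDAConfig:
    n_records_per_gene: int = 4
    type_mix: tuple[str, ...] = ("disease", "phenotype", "group")
    # score grid deliberately straddles the 0.3 strict cutoff
    score_grid: tuple[float, ...] = (0.29, 0.30, 0.31, 0.45, 0.60, 0.90)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    genome: GenomeConfig = GenomeConfig()
    annotation: AnnotationConfig = AnnotationConfig()
    network: NetworkConfig = NetworkConfig()
    gda: GDAConfig = GDAConfig()


_STREAMS = {"genome": 1, "annotation": 2, "network": 3, "gda": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


# ---------------------------------------------------------------------------
# truth container

@dataclass
class SyntheticTruth:
    """Machine-readable ground truth for one generated fixture."""

    planted_sites: list[GenomicSite] = field(default_factory=list)
    expected_associations: list[tuple[int, str, str]] = field(default_factory=list)
    gene_classes: dict[str, str] = field(default_factory=dict)
    kinase_set: list[str] = field(default_factory=list)
    expected_query_counts: dict[str, int] = field(default_factory=dict)
    bridge_node: Optional[str] = None
    expected_gda_kept: list[str] = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        d = {
            "planted_sites": [asdict(s) for s in self.planted_sites],
            "expected_associations": [list(t) for t in self.expected_associations],
            "gene_classes": self.gene_classes,
            "kinase_set": self.kinase_set,
            "expected_query_counts": self.expected_query_counts,
            "bridge_node": self.bridge_node,
            "expected_gda_kept": self.expected_gda_kept,
        }
        return json.dumps(d, indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            planted_sites=[GenomicSite(**s) for s in d["planted_sites"]],
            expected_associations=[tuple(t) for t in d["expected_associations"]],
            gene_classes=d["gene_classes"],
            kinase_set=d["kinase_set"],
            expected_query_counts=d["expected_query_counts"],
            bridge_node=d["bridge_node"],
            expected_gda_kept=d["expected_gda_kept"],
        )


# ---------------------------------------------------------------------------
# naive oracles (independent of the production scan / association paths)

def _matches_at(pattern_text: str, seq: str, pos: int) -> bool:
    for i, pch in enumerate(pattern_text):
        gset = IUPAC_SETS.get(seq[pos + i].upper())
        if gset is None or not gset <= IUPAC_SETS[pch]:
            return False
    return True


def naive_scan(pattern_text: str, seq: str) -> list[tuple[int, str]]:
    """O(n*m) position-by-position scan; returns (start, strand) pairs."""
    m = len(pattern_text)
    rc = reverse_complement(pattern_text).upper()
    hits = []
    for pos in range(len(seq) - m + 1):
        if _matches_at(pattern_text, seq, pos):
            hits.append((pos, "+"))
        if _matches_at(rc, seq, pos):
            hits.append((pos, "-"))
    return hits


def naive_associate(
    sites: Sequence[GenomicSite],
    genes: Sequence[GeneRecord],
    window: AssociationWindow,
) -> list[tuple[int, str, str]]:
    """All-pairs window-overlap oracle; returns (site index, symbol, relation)."""
    out = []
    for si, site in enumerate(sites):
        if window.orientation_mode == "forward-fixed" or site.strand == "+":
            lo = site.start - window.upstream_bp
            hi = site.end + window.downstream_bp
        else:
            lo = site.start - window.downstream_bp
            hi = site.end + window.upstream_bp
        lo = max(lo, 0)
        for g in genes:
            if g.chrom != site.chrom or not (g.start < hi and lo < g.end):
                continue
            if g.start < site.end and site.start < g.end:
                rel = "overlaps-site"
            elif (g.start >= site.end) == (site.strand != "-"):
                rel = "downstream-window"
            else:
                rel = "upstream-window"
            out.append((si, g.symbol, rel))
    return out


# ---------------------------------------------------------------------------
# genome

_BASES = np.array(list("ACGT"))


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p)


def _scrub(chars: np.ndarray, pattern_text: str, rng: np.random.Generator,
           protect: Sequence[tuple[int, int]] = ()) -> None:
    """Destroy every chance motif occurrence (either strand) in place by
    single-base substitution, leaving ``protect`` intervals untouched."""
    m = len(pattern_text)
    rc = reverse_complement(pattern_text).upper()
    # most-constrained pattern offset: substituting outside its base class
    # is guaranteed to break a match at that orientation
    off_f = min(range(m), key=lambda i: len(IUPAC_SETS[pattern_text[i]]))
    off_r = min(range(m), key=lambda i: len(IUPAC_SETS[rc[i]]))
    for _ in range(50):
        seq = "".join(chars)
        hits = [h for h in naive_scan(pattern_text, seq)
                if not any(p0 < h[0] + m and h[0] < p1 for p0, p1 in protect)]
        if not hits:
            return
        for pos, strand in hits:
            off = pos + (off_f if strand == "+" else off_r)
            forbid = IUPAC_SETS[(pattern_text if strand == "+" else rc)[off - pos]]
            choices = [b for b in "ACGT" if b not in forbid] or \
                      [b for b in "ACGT" if b != chars[off]]
            chars[off] = choices[int(rng.integers(len(choices)))]
    raise RuntimeError("background scrubbing did not converge")


def generate_genome(
    config: GeneratorConfig,
    pattern: IUPACPattern | str = DEFAULT_MOTIF,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Genome records with planted motif occurrences and their truth.

    Planted sites are non-overlapping, at least one pattern length apart;
    ``+`` sites carry the consensus with each degenerate position filled
    by a random base, ``-`` sites its reverse complement.  With
    ``scrub_background`` (default) chance background occurrences are
    destroyed first, so a scan recovers exactly the planted set — this is
    verified against the naive oracle before returning.
    """
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    gcfg = config.genome
    if len(gcfg.lengths) != gcfg.n_chromosomes:
        raise ValueError("lengths must list one length per chromosome")
    m = pattern.length
    n_total = gcfg.n_planted_plus + gcfg.n_planted_minus
    rng = _rng(config.seed, "genome")
    records: list[SequenceRecord] = []
    truth = SyntheticTruth()

    # distribute planted sites round-robin over chromosomes
    strands = ["+"] * gcfg.n_planted_plus + ["-"] * gcfg.n_planted_minus
    rng.shuffle(strands)
    per_chrom: list[list[str]] = [[] for _ in range(gcfg.n_chromosomes)]
    for i, s in enumerate(strands):
        per_chrom[i % gcfg.n_chromosomes].append(s)

    for ci in range(gcfg.n_chromosomes):
        length = gcfg.lengths[ci]
        want = per_chrom[ci]
        if length < m * max(1, len(want)) * 2:
            raise ValueError(
                f"chromosome length {length} cannot pack {len(want)} sites"
            )
        chrom = f"chr{ci + 1}"
        for _attempt in range(20):
            chars = _random_background(rng, length, gcfg.gc_fraction)
            # non-overlapping starts, pairwise gap >= pattern length
            starts: list[int] = []
            tries = 0
            while len(starts) < len(want) and tries < 100_000:
                tries += 1
                cand = int(rng.integers(0, length - m + 1))
                if all(abs(cand - s) >= 2 * m for s in starts):
                    starts.append(cand)
            if len(starts) < len(want):
                continue
            starts.sort()
            planted: list[tuple[int, str, str]] = []
            for start, strand in zip(starts, want):
                inst = "".join(
                    ch if ch != "N" else str(rng.choice(_BASES))
                    for ch in pattern.text
                )
                fwd = inst if strand == "+" else reverse_complement(inst)
                chars[start:start + m] = list(fwd)
                planted.append((start, strand, fwd))
            if gcfg.scrub_background:
                protect = [(s, s + m) for s, _, _ in planted]
                _scrub(chars, pattern.text, rng, protect)
                seq = "".join(chars)
                found = set(naive_scan(pattern.text, seq))
                if found != {(s, st) for s, st, _ in planted}:
                    continue  # junction artifact overlapping a planted site: retry
            else:
                seq = "".join(chars)
            records.append(SequenceRecord(chrom, seq))
            for start, strand, fwd in planted:
                truth.planted_sites.append(
                    GenomicSite(chrom, start, start + m, strand, fwd)
                )
            break
        else:
            raise RuntimeError(f"could not plant sites on {chrom}")
    truth.planted_sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    assert len(truth.planted_sites) == n_total
    return records, truth


# ---------------------------------------------------------------------------
# annotation

def generate_annotation(
    truth: SyntheticTruth,
    config: GeneratorConfig,
    records: Sequence[SequenceRecord],
    window: AssociationWindow = AssociationWindow(),
) -> list[GeneRecord]:
    """Genes at controlled distances from each planted site.

    Per site: ``n_genes_inside_window`` strictly inside the window (the
    first of them is designated a kinase and added to the fixture's gene
    set), one one-base-in / one first-base-out boundary pair when
    ``n_genes_boundary`` is set, and ``n_genes_outside`` strictly outside.
    ``expected_associations`` in the truth is then computed with the
    all-pairs oracle over every placed gene and every planted site, so it
    stays exact even when neighboring site windows overlap.
    """
    acfg = config.annotation
    rng = _rng(config.seed, "annotation")
    lengths = {r.id: len(r.residues) for r in records}
    genes: list[GeneRecord] = []

    def glen() -> int:
        lo, hi = acfg.gene_length_range
        return int(rng.integers(lo, hi + 1))

    for si, site in enumerate(truth.planted_sites):
        L = lengths[site.chrom]
        if window.orientation_mode == "forward-fixed" or site.strand == "+":
            lo = site.start - window.upstream_bp
            hi = site.end + window.downstream_bp
        else:
            lo = site.start - window.downstream_bp
            hi = site.end + window.upstream_bp
        lo = max(lo, 0)
        hi = min(hi, L)

        def add(start: int, end: int, symbol: str, klass: str) -> None:
            start, end = max(start, 0), min(end, L)
            if start >= end:
                return
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(site.chrom, start, end, strand, symbol))
            truth.gene_classes[symbol] = klass

        for j in range(acfg.n_genes_inside_window):
            gl = glen()
            span = (hi - 1) - lo - gl
            if span <= 0:
                continue
            start = lo + 1 + int(rng.integers(span))
            symbol = f"KIN{si}" if j == 0 else f"GENE{si}_{j}"
            add(start, start + gl, symbol, "inside")
            if j == 0:
                truth.kinase_set.append(symbol)
        if acfg.n_genes_boundary:
            gl = glen()
            # last covered base is hi - 1: one base inside the half-open window
            add(hi - 1, hi - 1 + gl, f"BIN{si}", "boundary-in")
            # first base exactly at hi: outside
            add(hi, hi + gl, f"BOUT{si}", "boundary-out")
        for j in range(acfg.n_genes_outside):
            gl = glen()
            start = hi + window.downstream_bp + 1 + int(rng.integers(5_000))
            add(start, start + gl, f"OUT{si}_{j}", "outside")

    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.symbol))
    truth.expected_associations = sorted(
        set(naive_associate(truth.planted_sites, genes, window))
    )
    return genes


# ---------------------------------------------------------------------------
# network

def generate_network(
    config: GeneratorConfig,
    queries: Sequence[str],
    truth: Optional[SyntheticTruth] = None,
) -> tuple[list[tuple[str, str, float]], SyntheticTruth]:
    """Scored edge triples with exact post-threshold per-query counts.

    Query i gets exactly ``per_query_planted_degrees[i]`` partners with
    confidence >= 0.7 (the first partner pinned at exactly 0.70 to
    exercise the inclusive boundary) plus sub-threshold partners that
    must be dropped.  Background edges connect only non-query nodes.  The
    highest-degree query is wired as a bridge to one partner of every
    other connected query, making it the known top hub under degree,
    closeness, and betweenness on the thresholded neighborhood.
    """
    ncfg = config.network
    if truth is None:
        truth = SyntheticTruth()
    queries = list(queries)
    if len(queries) != len(ncfg.per_query_planted_degrees):
        raise ValueError("one planted degree required per query")
    rng = _rng(config.seed, "network")
    edges: list[tuple[str, str, float]] = []
    partners: dict[str, list[str]] = {}

    def u(lo_hi: tuple[float, float]) -> float:
        return round(float(rng.uniform(*lo_hi)), 3)

    for qi, (q, deg) in enumerate(zip(queries, ncfg.per_query_planted_degrees)):
        partners[q] = [f"P{qi}_{j}" for j in range(deg)]
        for j, p in enumerate(partners[q]):
            score = 0.70 if j == 0 else u(ncfg.high_score_range)
            edges.append((q, p, score))
        for j in range(ncfg.n_low_confidence_per_query):
            edges.append((q, f"P{qi}_LOW{j}", u(ncfg.low_score_range)))

    degs = list(ncfg.per_query_planted_degrees)
    bridge = queries[int(np.argmax(degs))] if any(degs) else None
    n_bridged = 0
    if bridge is not None:
        for q in queries:
            if q != bridge and partners[q]:
                edges.append((bridge, partners[q][0], u(ncfg.high_score_range)))
                n_bridged += 1

    bg = [f"BG{j}" for j in range(ncfg.n_background_nodes)]
    for i in range(len(bg)):
        for j in range(i + 1, len(bg)):
            if rng.random() < ncfg.background_edge_prob:
                edges.append((bg[i], bg[j], u(ncfg.background_score_range)))

    # truth by construction, then validated by an adjacency recount oracle
    counts = {q: d for q, d in zip(queries, ncfg.per_query_planted_degrees)}
    recount: dict[str, set[str]] = {q: set() for q in queries}
    for a, b, c in edges:
        if c >= 0.7:
            if a in recount:
                recount[a].add(b)
            if b in recount:
                recount[b].add(a)
    assert {q: len(v) for q, v in recount.items()} == {
        q: counts[q] + (n_bridged if q == bridge else 0) for q in queries
    }
    truth.expected_query_counts = {q: len(recount[q]) for q in queries}
    truth.bridge_node = bridge
    return edges, truth


# ---------------------------------------------------------------------------
# gene-disease table

def generate_gda(
    config: GeneratorConfig,
    genes: Sequence[str],
    truth: Optional[SyntheticTruth] = None,
) -> tuple[list[GDARecord], SyntheticTruth]:
    """GDA records on a score grid straddling the 0.3 cutoff, with a
    disease-type mix including ``phenotype``; truth lists the
    ``gene:disease`` keys that survive the default strict filter."""
    gcfg = config.gda
    if truth is None:
        truth = SyntheticTruth()
    rng = _rng(config.seed, "gda")
    records: list[GDARecord] = []
    kept: list[str] = []
    k = 0
    for gene in genes:
        for _ in range(gcfg.n_records_per_gene):
            score = float(gcfg.score_grid[int(rng.integers(len(gcfg.score_grid)))])
            dtype = gcfg.type_mix[k % len(gcfg.type_mix)]
            disease = f"synthetic disease {k:04d}"
            records.append(GDARecord(gene, disease, dtype, score))
            if score > 0.3 and dtype.casefold() != "phenotype":
                kept.append(f"{gene}:{disease}")
            k += 1
    truth.expected_gda_kept = sorted(kept)
    return records, truth


# ---------------------------------------------------------------------------
# whole-fixture emission

def kinase_panel_config(seed: int = 0) -> GeneratorConfig:
    """Preset echoing the real study's shape: 29 query kinases whose
    planted interactor degrees follow the reported per-kinase spread."""
    # 29 planted sites: one kinase-class gene per site, so the full 29-gene
    # query panel flows genome -> association -> gene-set filter -> network
    return GeneratorConfig(
        seed=seed,
        genome=GenomeConfig(n_chromosomes=2, lengths=(150_000, 120_000),
                            n_planted_plus=15, n_planted_minus=14),
        network=NetworkConfig(per_query_planted_degrees=TABLE1_DEGREES,
                              n_background_nodes=60),
    )


def write_fixture(
    config: GeneratorConfig,
    out_dir,
    pattern: IUPACPattern | str = DEFAULT_MOTIF,
    window: AssociationWindow = AssociationWindow(),
    queries: Optional[Sequence[str]] = None,
) -> Path:
    """Generate all stages and write FASTA / BED / TSVs / truth JSON.

    ``queries`` defaults to the fixture's own planted kinase symbols
    (kinase-panel configs override this with the 29 kinase names).
    Returns the output directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = generate_genome(config, pattern)
    genes = generate_annotation(truth, config, records, window)

    if queries is None:
        if len(config.network.per_query_planted_degrees) == len(TABLE1_DEGREES):
            queries = list(TABLE1_KINASES)
            # relabel planted kinases so the gene set flows into the network
            mapping = dict(zip(truth.kinase_set, queries))
            genes = [
                GeneRecord(g.chrom, g.start, g.end, g.strand,
                           mapping.get(g.symbol, g.symbol))
                for g in genes
            ]
            truth.expected_associations = [
                (si, mapping.get(sym, sym), rel)
                for si, sym, rel in truth.expected_associations
            ]
            truth.gene_classes = {
                mapping.get(s, s): k for s, k in truth.gene_classes.items()
            }
            truth.kinase_set = [mapping.get(s, s) for s in truth.kinase_set]
        else:
            queries = list(truth.kinase_set)[
                : len(config.network.per_query_planted_degrees)
            ]
            truth.kinase_set = list(queries)
    edges, truth = generate_network(config, queries, truth)
    gda_records, truth = generate_gda(config, queries, truth)

    with open(out / "genome.fa", "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 80):
                fh.write(rec.residues[i:i + 80] + "\n")
    with open(out / "genes.bed", "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\t0\t{g.strand}\n")
    with open(out / "geneset.txt", "w") as fh:
        for s in list(queries) + ["DECOY1", "DECOY2"]:
            fh.write(s + "\n")
    with open(out / "network.tsv", "w") as fh:
        fh.write("symbol_a\tsymbol_b\tconfidence\n")
        for a, b, c in edges:
            fh.write(f"{a}\t{b}\t{c}\n")
    with open(out / "gda.tsv", "w") as fh:
        fh.write("gene\tdisease_name\tdisease_type\tscore\n")
        for r in gda_records:
            fh.write(f"{r.gene}\t{r.disease_name}\t{r.disease_type}\t{r.score}\n")
    with open(out / "truth.json", "w") as fh:
        fh.write(truth.to_json() + "\n")
    return out
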