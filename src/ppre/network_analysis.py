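"""Scored PPI loading, query neighborhoods, and centrality-based hub calling.

The interactome is an undirected graph whose edges carry a confidence
score in [0, 1] (HIPPIE-style).  High-confidence analysis keeps edges
with score >= 0.7 (inclusive threshold).  The query gene set's direct
interaction neighborhood is extracted as an induced subgraph, per-query
interactor counts and the fraction of the reference interactome touched
are reported, and hub genes are called as the union / intersection of
the top-k nodes under degree, harmonic closeness, and (unnormalized)
shortest-path betweenness — the three cytoHubba-style measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "ScoredNetwork",
    "NeighborhoodReport",
    "HubReport",
    "load_scored_network",
    "build_scored_network",
    "neighborhood",
    "centrality_scores",
    "hub_genes",
    "coverage_percent",
]

DEFAULT_MIN_CONFIDENCE = 0.7
MEASURES = ("degree", "closeness", "betweenness")


@dataclass
class ScoredNetwork:
    """An undirected confidence-scored interaction network.

    ``graph`` holds the post-threshold edges (edge attribute
    ``confidence``); ``reference_node_count`` is the node count of the
    network before thresholding, the denominator used for interactome
    coverage (a flag at load time can switch it to the thresholded count).
    """

    graph: nx.Graph
    threshold_applied: Optional[float] = None
    reference_node_count: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NeighborhoodReport:
    """Interactor tallies for a query set against the network."""

    per_query_counts: dict[str, int]
    total_interactors: int          # distinct non-query interactors
    total_interactors_with_queries: int
    coverage_percent: float
    missing_queries: list[str] = field(default_factory=list)


@dataclass
class HubReport:
    """Top-k rankings per centrality measure plus union and intersection."""

    rankings: dict[str, list[tuple[str, float]]]
    top_k: int
    union_set: set[str]
    intersection_set: set[str]


def build_scored_network(
    edges: Iterable[tuple[str, str, float]],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    keep_isolated: bool = False,
    coverage_reference: str = "unthresholded",
) -> ScoredNetwork:
    """Assemble a :class:`ScoredNetwork` from (a, b, confidence) triples.

    Self-loops are dropped; duplicate undirected edges collapse keeping
    the maximum confidence; edges with confidence >= ``min_confidence``
    are retained.  With ``keep_isolated`` every node seen before
    thresholding stays in the graph even if all its edges were dropped.
    """
    if coverage_reference not in ("unthresholded", "thresholded"):
        raise ValueError(f"unknown coverage_reference {coverage_reference!r}")
    full = nx.Graph()
    for a, b, c in edges:
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"confidence {c} outside [0, 1] for edge ({a}, {b})")
        if a == b:
            continue
        if full.has_edge(a, b):
            full[a][b]["confidence"] = max(full[a][b]["confidence"], c)
        else:
            full.add_edge(a, b, confidence=c)
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(full.nodes)
    for a, b, data in full.edges(data=True):
        if data["confidence"] >= min_confidence:
            g.add_edge(a, b, confidence=data["confidence"])
    ref = full.number_of_nodes() if coverage_reference == "unthresholded" else g.number_of_nodes()
    return ScoredNetwork(graph=g, threshold_applied=min_confidence,
                         reference_node_count=ref)


def load_scored_network(
    path,
    dialect: str = "simple-tsv",
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    score_col: Optional[int] = None,
    **kwargs,
) -> ScoredNetwork:
    """Read a tab-separated scored edge list.

    ``simple-tsv``: two symbol columns then the confidence (``score_col``
    overrides the confidence column index).  ``hippie-tab``: the native
    HIPPIE layout — UniProt name A, Entrez A, UniProt name B, Entrez B,
    confidence, metadata; symbols are the UniProt names with the
    ``_HUMAN`` suffix stripped.  Symbols are uppercased in both dialects.
    """
    if dialect not in ("simple-tsv", "hippie-tab"):
        raise ValueError(f"unknown edge-list dialect {dialect!r}")

    def triples():
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                try:
                    if dialect == "hippie-tab":
                        a, b = fields[0], fields[2]
                        ci = 4 if score_col is None else score_col
                        a = a.removesuffix("_HUMAN")
                        b = b.removesuffix("_HUMAN")
                    else:
                        a, b = fields[0], fields[1]
                        ci = 2 if score_col is None else score_col
                    conf = float(fields[ci])
                except (IndexError, ValueError) as exc:
                    if lineno == 1:
                        continue  # tolerate a header row
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse confidence: {exc}"
                    ) from exc
                if not (0.0 <= conf <= 1.0):
                    raise ValueError(
                        f"{path}:{lineno}: confidence {conf} outside [0, 1]"
                    )
                if a and b:
                    yield a.upper(), b.upper(), conf

    return build_scored_network(triples(), min_confidence=min_confidence, **kwargs)


def neighborhood(
    network: ScoredNetwork,
    queries: Iterable[str],
    include_query_query_edges: bool = True,
) -> tuple[nx.Graph, NeighborhoodReport]:
    """Induced subgraph on the queries and their direct interactors.

    Per-query counts are distinct direct neighbors in the thresholded
    graph.  ``total_interactors`` excludes query genes themselves (the
    count including them is also reported); coverage is 100 x
    total_interactors / reference node count, to two decimals.
    """
    queries = sorted(set(queries))
    if not queries:
        raise ValueError("query set must be non-empty")
    g = network.graph
    missing = [q for q in queries if q not in g]
    per_query: dict[str, int] = {}
    interactors: set[str] = set()
    for q in queries:
        nbrs = set(g.neighbors(q)) if q in g else set()
        per_query[q] = len(nbrs)
        interactors |= nbrs
    qset = set(queries)
    non_query = interactors - qset
    members = qset | interactors
    sub = g.subgraph(m for m in members if m in g).copy()
    if not include_query_query_edges:
        sub.remove_edges_from(
            [(a, b) for a, b in sub.edges if a in qset and b in qset]
        )
    ref = network.reference_node_count
    cov = round(100.0 * len(non_query) / ref, 2) if ref else 0.0
    report = NeighborhoodReport(
        per_query_counts=per_query,
        total_interactors=len(non_query),
        total_interactors_with_queries=len(interactors),
        coverage_percent=cov,
        missing_queries=missing,
    )
    return sub, report


def coverage_percent(n_interactors: int, n_reference_nodes: int, ndigits: int = 2) -> float:
    """Interactome coverage: 100 x interactors / reference nodes, rounded."""
    if n_reference_nodes <= 0:
        raise ValueError("reference node count must be positive")
    return round(100.0 * n_interactors / n_reference_nodes, ndigits)


def centrality_scores(network: ScoredNetwork | nx.Graph, measure: str) -> dict[str, float]:
    """Node scores under one measure; paths are unweighted.

    degree: incident edge count.  closeness: harmonic form, the sum of
    reciprocal shortest-path distances to reachable nodes (finite on
    disconnected graphs).  betweenness: shortest-path betweenness with
    pair normalization disabled (raw pair counts).
    """
    g = network.graph if isinstance(network, ScoredNetwork) else network
    if measure == "degree":
        return {n: float(d) for n, d in g.degree()}
    if measure == "closeness":
        return {n: float(v) for n, v in nx.harmonic_centrality(g).items()}
    if measure == "betweenness":
        return {n: float(v)
                for n, v in nx.betweenness_centrality(g, normalized=False).items()}
    raise ValueError(f"unknown centrality measure {measure!r}")


def hub_genes(
    network: ScoredNetwork | nx.Graph,
    top_k: int = 10,
    measures: Iterable[str] = MEASURES,
    candidates: Optional[Iterable[str]] = None,
    warn: Optional[callable] = None,
) -> HubReport:
    """Top-k nodes per measure; union and intersection across measures.

    Rankings order by (score descending, symbol ascending); ties at the
    k-th rank are cut lexicographically, not expanded.  ``candidates``
    restricts the ranked nodes (e.g. to the query genes only); the
    default ranks every node of the graph, as cytoHubba does.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    g = network.graph if isinstance(network, ScoredNetwork) else network
    measures = list(measures)
    for m in measures:
        if m not in MEASURES:
            raise ValueError(f"unknown centrality measure {m!r}")
    pool = set(candidates) & set(g.nodes) if candidates is not None else set(g.nodes)
    if len(pool) < top_k and warn is not None:
        warn(f"only {len(pool)} candidate nodes for top_k={top_k}; truncating")
    rankings: dict[str, list[tuple[str, float]]] = {}
    tops: list[set[str]] = []
    for m in measures:
        scores = centrality_scores(g, m)
        ordered = sorted(((n, scores[n]) for n in pool),
                         key=lambda t: (-t[1], t[0]))
        rankings[m] = ordered[:top_k]
        tops.append({n for n, _ in rankings[m]})
    union = set().union(*tops) if tops else set()
    inter = set.intersection(*tops) if tops else set()
    return HubReport(rankings=rankings, top_k=top_k,
                     union_set=union, intersection_set=inter)
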