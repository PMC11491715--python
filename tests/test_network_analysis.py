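"""Thresholding, neighborhoods, and centrality hub calling vs BFS oracles."""

from collections import deque

import networkx as nx
import numpy as np
import pytest

from ppre.network_analysis import (
    HubReport,
    build_scored_network,
    centrality_scores,
    coverage_percent,
    hub_genes,
    load_scored_network,
    neighborhood,
)


# ---------------------------------------------------------------------------
# independent BFS oracles

def bfs_distances(g: nx.Graph, src):
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def oracle_harmonic_closeness(g: nx.Graph):
    out = {}
    for v in g.nodes:
        d = bfs_distances(g, v)
        out[v] = sum(1.0 / x for u, x in d.items() if u != v)
    return out


def oracle_betweenness(g: nx.Graph):
    """Raw pair-count betweenness by explicit shortest-path enumeration."""
    nodes = list(g.nodes)
    bt = {v: 0.0 for v in nodes}

    def all_shortest_paths(s, t):
        try:
            return list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            return []

    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bt[v] += through / len(paths)
    return bt


def random_graph(rng, n, p):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g


# ---------------------------------------------------------------------------

class TestBuildAndLoad:
    def test_inclusive_threshold_boundary(self):
        net = build_scored_network(
            [("A", "B", 0.70), ("A", "C", 0.699)], min_confidence=0.7
        )
        assert net.graph.has_edge("A", "B")
        assert not net.graph.has_edge("A", "C")

    def test_undirected_duplicate_keep_max(self):
        net = build_scored_network(
            [("A", "B", 0.8), ("B", "A", 0.9)], min_confidence=0.0
        )
        assert net.graph.number_of_edges() == 1
        assert net.graph["A"]["B"]["confidence"] == 0.9

    def test_self_loops_dropped_and_score_validated(self):
        net = build_scored_network([("A", "A", 0.9)], min_confidence=0.0)
        assert net.graph.number_of_edges() == 0
        with pytest.raises(ValueError, match="outside"):
            build_scored_network([("A", "B", 1.2)])

    def test_reference_node_count_modes(self):
        edges = [("A", "B", 0.9), ("C", "D", 0.5)]
        pre = build_scored_network(edges, 0.7, coverage_reference="unthresholded")
        post = build_scored_network(edges, 0.7, coverage_reference="thresholded")
        assert pre.reference_node_count == 4
        assert post.reference_node_count == 2

    def test_keep_isolated_retains_pre_threshold_nodes(self):
        edges = [("A", "B", 0.9), ("C", "D", 0.5)]
        assert build_scored_network(edges, 0.7).nodes == {"A", "B"}
        assert build_scored_network(edges, 0.7, keep_isolated=True).nodes == {
            "A", "B", "C", "D"
        }

    def test_load_simple_tsv_with_header(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("symbol_a\tsymbol_b\tconfidence\nfoo\tbar\t0.8\n")
        net = load_scored_network(p, min_confidence=0.7)
        assert net.graph.has_edge("FOO", "BAR")  # symbols uppercased

    def test_load_hippie_dialect(self, tmp_path):
        p = tmp_path / "hippie.tsv"
        p.write_text("AL1A1_HUMAN\t216\tAL1A1_HUMAN\t216\t0.76\tinfo\n"
                     "ITA7_HUMAN\t3679\tACHA_HUMAN\t1134\t0.73\tinfo\n"
                     "NEB1_HUMAN\t55607\tACTG_HUMAN\t71\t0.65\tinfo\n")
        net = load_scored_network(p, dialect="hippie-tab", min_confidence=0.7)
        assert net.graph.has_edge("ITA7", "ACHA")
        assert "NEB1" not in net.graph          # below threshold
        assert net.graph.number_of_edges() == 1  # self-loop dropped
        assert net.reference_node_count == 4

    def test_bad_confidence_reports_line(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t0.9\nC\tD\tnotanumber\n")
        with pytest.raises(ValueError, match=":2"):
            load_scored_network(p)


class TestNeighborhood:
    def star(self, n=5):
        return build_scored_network(
            [("C", f"L{i}", 0.9) for i in range(n)], min_confidence=0.7
        )

    def test_star_center_and_leaf_counts(self):
        net = self.star()
        _, rep = neighborhood(net, {"C"})
        assert rep.per_query_counts == {"C": 5}
        _, rep = neighborhood(net, {"L1"})
        assert rep.per_query_counts == {"L1": 1}

    def test_isolated_query_counts_zero(self):
        net = self.star()
        _, rep = neighborhood(net, {"C", "GHOST"})
        assert rep.per_query_counts["GHOST"] == 0
        assert rep.missing_queries == ["GHOST"]

    def test_interactor_union_excludes_queries(self):
        net = build_scored_network(
            [("Q1", "Q2", 0.9), ("Q1", "X", 0.9), ("Q2", "X", 0.9)],
            min_confidence=0.7,
        )
        _, rep = neighborhood(net, {"Q1", "Q2"})
        assert rep.total_interactors == 1
        assert rep.total_interactors_with_queries == 3

    def test_coverage_against_reference_count(self):
        assert coverage_percent(1084, 19485) == 5.56
        net = self.star()
        _, rep = neighborhood(net, {"C"})
        assert rep.coverage_percent == round(100 * 5 / 6, 2)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        edges = [(f"N{i}", f"N{j}", float(rng.uniform(0, 1)))
                 for i in range(20) for j in range(i + 1, 20)
                 if rng.random() < 0.3]
        queries = ["N0", "N1", "N2"]
        prev = None
        for thr in (0.2, 0.5, 0.7, 0.9):
            net = build_scored_network(edges, thr, keep_isolated=True)
            _, rep = neighborhood(net, queries)
            if prev is not None:
                for q in queries:
                    assert rep.per_query_counts[q] <= prev[q]
            prev = rep.per_query_counts

    def test_induced_subgraph_includes_interactor_interactor_edges(self):
        net = build_scored_network(
            [("Q", "A", 0.9), ("Q", "B", 0.9), ("A", "B", 0.9),
             ("A", "FAR", 0.9)],
            min_confidence=0.7,
        )
        sub, _ = neighborhood(net, {"Q"})
        assert sub.has_edge("A", "B")
        assert "FAR" not in sub


class TestCentralities:
    def test_path_graph_closed_forms(self):
        g = nx.path_graph(["A", "B", "C"])
        assert centrality_scores(g, "degree")["B"] == 2
        assert centrality_scores(g, "betweenness")["B"] == 1.0
        assert centrality_scores(g, "closeness")["A"] == pytest.approx(1.5)

    def test_star_graph_closed_forms(self):
        g = nx.star_graph(5)  # center 0, leaves 1..5
        close = centrality_scores(g, "closeness")
        assert close[0] == pytest.approx(5.0)
        for leaf in range(1, 6):
            assert close[leaf] == pytest.approx(1 + 4 * 0.5)

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="measure"):
            centrality_scores(nx.path_graph(3), "pagerank")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_all_measures_equal_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        g = random_graph(rng, n, 0.15)  # sparse: often disconnected
        deg = centrality_scores(g, "degree")
        assert deg == {v: float(g.degree(v)) for v in g.nodes}
        close = centrality_scores(g, "closeness")
        oracle_c = oracle_harmonic_closeness(g)
        for v in g.nodes:
            assert close[v] == pytest.approx(oracle_c[v])
        bt = centrality_scores(g, "betweenness")
        oracle_b = oracle_betweenness(g)
        for v in g.nodes:
            assert bt[v] == pytest.approx(oracle_b[v])


class TestHubGenes:
    def test_identical_rankings_collapse(self):
        g = nx.path_graph(6)
        report = hub_genes(g, top_k=3, measures=["degree"])
        assert report.union_set == report.intersection_set

    def test_star_center_rank_one_everywhere(self):
        g = nx.star_graph(7)
        report = hub_genes(g, top_k=3)
        for ranking in report.rankings.values():
            assert ranking[0][0] == 0

    def test_union_intersection_vs_oracle_centralities(self):
        rng = np.random.default_rng(12)
        g = random_graph(rng, 12, 0.3)
        g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        k = 4
        report = hub_genes(g, top_k=k)
        oracle_rank = {}
        for name, fn in [
            ("degree", lambda: {v: float(g.degree(v)) for v in g.nodes}),
            ("closeness", lambda: oracle_harmonic_closeness(g)),
            ("betweenness", lambda: oracle_betweenness(g)),
        ]:
            scores = fn()
            ordered = sorted(scores, key=lambda v: (-round(scores[v], 9), v))
            oracle_rank[name] = set(ordered[:k])
        assert report.union_set == set().union(*oracle_rank.values())
        assert report.intersection_set == set.intersection(*oracle_rank.values())
        assert len(report.union_set) <= 3 * k
        assert report.intersection_set <= report.union_set

    def test_deterministic_lexicographic_tie_break(self):
        g = nx.Graph([("B", "A"), ("C", "D")])  # all degrees equal
        report = hub_genes(g, top_k=2, measures=["degree"])
        assert [n for n, _ in report.rankings["degree"]] == ["A", "B"]

    def test_candidate_restriction_and_truncation(self):
        g = nx.star_graph(5)
        report = hub_genes(g, top_k=3, candidates=[1, 2])
        assert all(len(r) == 2 for r in report.rankings.values())
        warnings = []
        hub_genes(g, top_k=10, warn=warnings.append)
        assert warnings and "truncat" in warnings[0]

    def test_permutation_symmetry(self):
        rng = np.random.default_rng(4)
        g = random_graph(rng, 15, 0.25)
        g = nx.relabel_nodes(g, {i: f"A{i:02d}" for i in g.nodes})
        # order-preserving relabeling: scores permute, rankings follow
        mapping = {n: n.replace("A", "Z") for n in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        for measure in ("degree", "closeness", "betweenness"):
            sg = centrality_scores(g, measure)
            sh = centrality_scores(h, measure)
            assert {mapping[n]: s for n, s in sg.items()} == pytest.approx(sh)
        rg = hub_genes(g, top_k=5)
        rh = hub_genes(h, top_k=5)
        assert {mapping[n] for n in rg.union_set} == rh.union_set
        assert {mapping[n] for n in rg.intersection_set} == rh.intersection_set
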