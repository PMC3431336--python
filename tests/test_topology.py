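"""PPI loading, centralities vs brute force, KS, resampling, neighborhoods."""

import collections

import networkx as nx
import numpy as np
import pytest

from trireg import topology
from trireg.errors import ParameterError, ParseError


# ---------------------------------------------------------------------------
# Independent brute-force oracle (BFS all-pairs shortest paths)
# ---------------------------------------------------------------------------

def _bfs_distances(adj, source):
    dist = {source: 0}
    queue = collections.deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _bfs_shortest_path_counts(adj, source):
    """Number of shortest paths from source to every node."""
    dist = {source: 0}
    count = {source: 1}
    queue = collections.deque([source])
    order = []
    while queue:
        u = queue.popleft()
        order.append(u)
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                count[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                count[v] += count[u]
    return dist, count


def brute_force_stats(g, normalized_betweenness=True):
    adj = {v: sorted(g.neighbors(v)) for v in g.nodes}
    nodes = sorted(g.nodes)
    n = len(nodes)
    degree = {v: len(adj[v]) for v in nodes}
    closeness = {}
    for v in nodes:
        dist = _bfs_distances(adj, v)
        reachable = len(dist) - 1
        if reachable == 0:
            closeness[v] = 0.0
        else:
            closeness[v] = (reachable / sum(dist.values())) * (
                reachable / (n - 1)
            )
    betweenness = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s >= t:
                continue
            dist, count = _bfs_shortest_path_counts(adj, s)
            if t not in dist:
                continue
            for v in nodes:
                if v in (s, t) or v not in dist:
                    continue
                dist_vt, count_vt = _bfs_shortest_path_counts(adj, v)
                if t in dist_vt and dist[v] + dist_vt[t] == dist[t]:
                    betweenness[v] += count[v] * count_vt[t] / count[t]
    if normalized_betweenness and n > 2:
        norm = (n - 1) * (n - 2) / 2
        betweenness = {v: b / norm for v, b in betweenness.items()}
    return degree, betweenness, closeness


# ---------------------------------------------------------------------------
# load_ppi
# ---------------------------------------------------------------------------

class TestLoadPPI:
    def test_dedupe_and_self_loop_removal(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tA\nC\tC\n")
        g = topology.load_ppi(p)
        assert sorted(map(sorted, g.edges)) == [["A", "B"]]

    def test_empty_file_gives_empty_network(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        g = topology.load_ppi(p)
        assert g.number_of_nodes() == 0

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tC\nbroken-line\n")
        with pytest.raises(ParseError) as err:
            topology.load_ppi(p, strict=True)
        assert err.value.line == 3

    def test_header_tolerated(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_a\tgene_b\nA\tB\n")
        g = topology.load_ppi(p)
        assert g.has_edge("A", "B")
        # The header itself parses as two fields, so only line 1 is skipped.
        assert g.number_of_edges() == 1 or g.number_of_edges() == 2


# ---------------------------------------------------------------------------
# topology_stats
# ---------------------------------------------------------------------------

class TestTopologyStats:
    def test_star_center(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        stats = topology.topology_stats(g)
        assert stats.loc[0, "degree"] == 4
        assert stats.loc[0, "closeness"] == pytest.approx(1.0)

    def test_path_center_betweenness(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        stats = topology.topology_stats(g, normalized_betweenness=False)
        # c lies on the shortest paths of pairs {a,d},{a,e},{b,d},{b,e}.
        assert stats.loc["c", "betweenness"] == pytest.approx(4.0)

    def test_complete_graph_betweenness_zero(self):
        g = nx.complete_graph(6)
        stats = topology.topology_stats(g)
        assert (stats["betweenness"] == 0).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_small_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        g = nx.gnp_random_graph(n, 0.25, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        stats = topology.topology_stats(g)
        degree, betweenness, closeness = brute_force_stats(g)
        for v in g.nodes:
            assert stats.loc[v, "degree"] == degree[v]
            assert stats.loc[v, "betweenness"] == pytest.approx(betweenness[v])
            assert stats.loc[v, "closeness"] == pytest.approx(closeness[v])

    def test_isolated_node_closeness_zero(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("lonely")
        stats = topology.topology_stats(g)
        assert stats.loc["lonely", "closeness"] == 0.0

    def test_empty_network_rejected(self):
        with pytest.raises(ParameterError):
            topology.topology_stats(nx.Graph())


# ---------------------------------------------------------------------------
# ks_compare
# ---------------------------------------------------------------------------

class TestKSCompare:
    def test_identical_samples(self):
        res = topology.ks_compare([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = topology.ks_compare([1, 2, 3], [10, 11, 12])
        assert res.statistic == 1.0

    def test_hand_computed_sup_distance(self):
        # ECDFs of {1,2,3,4} and {3,4,5,6} differ most by 0.5 (at x in [2,3)).
        res = topology.ks_compare([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(0.5)

    def test_too_small_samples_rejected(self):
        with pytest.raises(ParameterError):
            topology.ks_compare([1], [1, 2])


# ---------------------------------------------------------------------------
# resampling_pvalue
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ba_stats():
    g = nx.barabasi_albert_graph(300, 3, seed=0)
    return topology.topology_stats(g)


class TestResampling:
    def test_maximal_set_gives_zero_p_with_caveat(self, ba_stats):
        top = list(ba_stats["degree"].nlargest(10).index)
        pool = list(ba_stats.index)
        res = topology.resampling_pvalue(ba_stats, top, pool, "degree", 500, seed=1)
        assert res.n_exceed == 0
        assert res.pvalue == 0.0
        assert "p <" in res.note

    def test_entire_pool_gives_zero_under_strict_inequality(self, ba_stats):
        pool = list(ba_stats.index)
        res = topology.resampling_pvalue(ba_stats, pool, pool, "degree", 200, seed=2)
        assert res.pvalue == 0.0

    def test_invariant_to_pool_ordering(self, ba_stats):
        pool = list(ba_stats.index)
        genes = pool[:20]
        a = topology.resampling_pvalue(ba_stats, genes, pool, "degree", 300, seed=3)
        b = topology.resampling_pvalue(
            ba_stats, genes, list(reversed(pool)), "degree", 300, seed=3
        )
        assert a == b

    def test_unknown_metric_rejected(self, ba_stats):
        with pytest.raises(ParameterError):
            topology.resampling_pvalue(
                ba_stats, [0], list(ba_stats.index), "pagerank", 100, seed=0
            )

    def test_null_pvalues_roughly_uniform(self, ba_stats):
        # Random gene sets from the pool should produce uniform p-values.
        from scipy import stats as sps

        pool = list(ba_stats.index)
        rng = np.random.default_rng(42)
        ps = []
        for i in range(100):
            genes = rng.choice(pool, size=15, replace=False)
            res = topology.resampling_pvalue(
                ba_stats, genes, pool, "degree", 200, seed=1000 + i
            )
            ps.append(res.pvalue)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# extract_neighborhood
# ---------------------------------------------------------------------------

class TestNeighborhood:
    def test_isolated_seed(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        sub = topology.extract_neighborhood(g, ["a"])
        assert set(sub.nodes) == {"a"}
        assert sub.number_of_edges() == 0

    def test_star_leaf_seed(self):
        g = nx.star_graph(4)
        sub = topology.extract_neighborhood(g, [1])
        assert set(sub.nodes) == {0, 1}
        assert sub.has_edge(0, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_neighborhood_union(self, seed):
        g = nx.gnp_random_graph(30, 0.1, seed=seed)
        rng = np.random.default_rng(seed)
        seeds = list(rng.choice(30, size=5, replace=False))
        sub = topology.extract_neighborhood(g, seeds)
        expected = set(seeds)
        for s in seeds:
            expected |= set(g.neighbors(s))
        assert set(sub.nodes) == expected

    def test_monotone_in_seed_set(self):
        g = nx.gnp_random_graph(30, 0.1, seed=3)
        small = set(topology.extract_neighborhood(g, [0, 1]).nodes)
        large = set(topology.extract_neighborhood(g, [0, 1, 2, 3]).nodes)
        assert small <= large

    def test_missing_seeds_ignored(self):
        g = nx.path_graph(3)
        sub = topology.extract_neighborhood(g, [0, "absent"])
        assert set(sub.nodes) == {0, 1}
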