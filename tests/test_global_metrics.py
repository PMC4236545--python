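import networkx as nx
import numpy as np
import pytest

from villagenet import betweenness_norm, brokerage, closeness_norm, degree
from villagenet.global_metrics import ROLES, brokerage_frame


def random_digraph(rng, n=None, p=None):
    n = n or int(rng.integers(5, 61))
    p = p or float(rng.uniform(0.05, 0.3))
    edges = [
        (int(i), int(j))
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return list(range(n)), edges


STAR = (list("cabd"), [("c", "a"), ("c", "b"), ("c", "d")])  # undirected star, center c


class TestDegree:
    def test_single_tie(self):
        df = degree((["a", "b"], [("a", "b")]))
        assert df.loc["a", "out_degree"] == 1 and df.loc["b", "in_degree"] == 1
        assert df.loc["a", "in_degree"] == 0 and df.loc["b", "out_degree"] == 0

    def test_empty_network(self):
        df = degree((["a", "b"], []))
        assert (df == 0).all().all()

    def test_matches_reference_on_random_digraph(self):
        rng = np.random.default_rng(1)
        nodes, edges = random_digraph(rng, n=50)
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        df = degree((nodes, edges))
        for u in nodes:
            assert df.loc[u, "in_degree"] == g.in_degree(u)
            assert df.loc[u, "out_degree"] == g.out_degree(u)


class TestCloseness:
    def test_star_center_has_maximum(self):
        c = closeness_norm(STAR)
        assert c["c"] == pytest.approx(1.0)

    def test_isolate_scores_zero(self):
        c = closeness_norm((["a", "b", "z"], [("a", "b")]))
        assert c["z"] == 0.0

    def test_matches_bfs_oracle_on_connected_graph(self):
        rng = np.random.default_rng(2)
        g = nx.connected_watts_strogatz_graph(30, 4, 0.3, seed=5)
        edges = [(u, v) for u, v in g.edges]
        mine = closeness_norm((list(g.nodes), edges))
        # independent all-pairs BFS oracle
        for u in g.nodes:
            dist = nx.single_source_shortest_path_length(g, u)
            expected = (len(g) - 1) / sum(dist.values())
            assert mine[u] == pytest.approx(expected, abs=1e-12)

    def test_wf_variant_matches_reference_on_disconnected_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            nodes, edges = random_digraph(rng)
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            ref = nx.closeness_centrality(g.to_undirected(), wf_improved=True)
            mine = closeness_norm((nodes, edges))
            for u in nodes:
                assert mine[u] == pytest.approx(ref[u], abs=1e-12)

    def test_harmonic_variant_bounds(self):
        rng = np.random.default_rng(4)
        nodes, edges = random_digraph(rng, n=20)
        vals = closeness_norm((nodes, edges), variant="harmonic")
        assert all(0.0 <= v <= 1.0 for v in vals.values())


class TestBetweenness:
    def test_star_center_is_one(self):
        b = betweenness_norm(STAR)
        assert b["c"] == pytest.approx(1.0)

    def test_tree_leaves_are_zero(self):
        g = nx.balanced_tree(2, 3)
        leaves = [u for u in g.nodes if g.degree(u) == 1]
        b = betweenness_norm((list(g.nodes), list(g.edges)))
        assert all(b[u] == 0.0 for u in leaves)

    def test_matches_brandes_reference(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            nodes, edges = random_digraph(rng)
            g = nx.DiGraph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            ref = nx.betweenness_centrality(g.to_undirected(), normalized=True)
            mine = betweenness_norm((nodes, edges))
            for u in nodes:
                assert mine[u] == pytest.approx(ref[u], abs=1e-12)

    def test_directed_mode_matches_reference(self):
        rng = np.random.default_rng(6)
        nodes, edges = random_digraph(rng, n=25)
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        ref = nx.betweenness_centrality(g, normalized=True)
        mine = betweenness_norm((nodes, edges), directed=True)
        for u in nodes:
            assert mine[u] == pytest.approx(ref[u], abs=1e-12)


def brokerage_oracle(nodes, edges, groups, mode):
    """Exhaustive enumeration over ordered triads."""
    E = set(edges)
    out = {u: dict.fromkeys(ROLES, 0) for u in nodes}
    for i in nodes:
        for j in nodes:
            for k in nodes:
                if len({i, j, k}) < 3 or (j, i) not in E or (i, k) not in E:
                    continue
                if mode == "excluded" and ((j, k) in E or (k, j) in E):
                    continue
                gi, gj, gk = groups[i], groups[j], groups[k]
                if gj == gi == gk:
                    r = "coordinator"
                elif gj != gi and gi == gk:
                    r = "gatekeeper"
                elif gj == gi and gi != gk:
                    r = "representative"
                elif gj == gk:
                    r = "itinerant"
                else:
                    r = "liaison"
                out[i][r] += 1
    return out


class TestBrokerage:
    def _triad(self, groups, extra_edges=()):
        nodes = ["j", "i", "k"]
        edges = [("j", "i"), ("i", "k")] + list(extra_edges)
        return brokerage((nodes, edges), groups)

    def test_same_district_two_path_is_coordinator(self):
        counts = self._triad({"j": "A", "i": "A", "k": "A"})
        assert counts["i"].coordinator == 1 and counts["i"].total == 1
        assert counts["j"].total == 0 and counts["k"].total == 0

    def test_outsider_to_insider_is_gatekeeper(self):
        counts = self._triad({"j": "B", "i": "A", "k": "A"})
        assert counts["i"].gatekeeper == 1 and counts["i"].total == 1

    def test_insider_to_outsider_is_representative(self):
        counts = self._triad({"j": "A", "i": "A", "k": "B"})
        assert counts["i"].representative == 1 and counts["i"].total == 1

    def test_direct_tie_suppresses_default_but_not_classic(self):
        nodes = ["j", "i", "k"]
        edges = [("j", "i"), ("i", "k"), ("j", "k")]
        groups = {"j": "A", "i": "A", "k": "A"}
        default = brokerage((nodes, edges), groups, mode="excluded")
        classic = brokerage((nodes, edges), groups, mode="classic")
        assert default["i"].total == 0
        assert classic["i"].coordinator == 1

    def test_single_group_only_coordinates(self):
        rng = np.random.default_rng(7)
        nodes, edges = random_digraph(rng, n=25)
        groups = {u: "only" for u in nodes}
        for counts in brokerage((nodes, edges), groups).values():
            assert counts.gatekeeper == counts.representative == 0
            assert counts.itinerant == counts.liaison == 0

    @pytest.mark.parametrize("mode", ["excluded", "classic"])
    def test_matches_exhaustive_triad_oracle(self, mode):
        rng = np.random.default_rng(8)
        for _ in range(10):
            nodes, edges = random_digraph(rng, n=int(rng.integers(5, 30)))
            groups = {u: f"g{int(rng.integers(0, 5))}" for u in nodes}
            ref = brokerage_oracle(nodes, edges, groups, mode)
            mine = brokerage((nodes, edges), groups, mode=mode)
            for u in nodes:
                assert {r: getattr(mine[u], r) for r in ROLES} == ref[u]

    def test_roles_partition_qualifying_two_paths(self):
        rng = np.random.default_rng(9)
        nodes, edges = random_digraph(rng, n=40)
        E = set(edges)
        groups = {u: f"g{int(rng.integers(0, 4))}" for u in nodes}
        counts = brokerage((nodes, edges), groups, mode="classic")
        for i in nodes:
            n_paths = sum(
                1
                for (j, i2) in E
                if i2 == i
                for (i3, k) in E
                if i3 == i and k != j and k != i and j != i
            )
            assert counts[i].total == n_paths

    def test_missing_district_raises(self):
        with pytest.raises(KeyError, match="i"):
            brokerage((["i", "j"], [("j", "i")]), {"j": "A"})

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(10)
        nodes, edges = random_digraph(rng, n=20)
        groups = {u: f"g{u % 3}" for u in nodes}
        mapping = {u: f"n{u:02d}" for u in nodes}
        relabeled = brokerage(
            ([mapping[u] for u in nodes], [(mapping[u], mapping[v]) for u, v in edges]),
            {mapping[u]: g for u, g in groups.items()},
        )
        original = brokerage((nodes, edges), groups)
        for u in nodes:
            assert original[u] == relabeled[mapping[u]]
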