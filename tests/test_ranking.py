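"""Centrality techniques, DEMATEL and the cluster cut point.

The networkx-backed centralities are checked against independent
brute-force oracles (exhaustive path enumeration, BFS distances, power
iteration on the raw adjacency matrix); DEMATEL is checked against the
truncated Neumann series, which is exact for acyclic (nilpotent) maps.
"""

from collections import deque

import numpy as np
import pytest
from hypothesis import given

from cldsynth import (
    CldError,
    NoClusterError,
    dematel,
    find_cluster_cutpoint,
    rank,
)
from cldsynth.ranking import TECHNIQUES

from conftest import diagram_from_edges, random_digraph, small_diagrams

# ---------------------------------------------------------------------------
# oracles


def bfs_distances(d, source):
    """Directed BFS distances over the diagram's edges (self-loops ignored)."""
    adj = {}
    for e in d.edges:
        if not e.is_self_loop:
            adj.setdefault(e.source, set()).add(e.target)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_betweenness(d):
    """Exhaustive enumeration of all shortest directed paths, DFS-based."""
    adj = {}
    for e in d.edges:
        if not e.is_self_loop:
            adj.setdefault(e.source, set()).add(e.target)
    nodes = sorted(d.variables)
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        dist = bfs_distances(d, s)
        for t in nodes:
            if t == s or t not in dist:
                continue
            paths = []
            stack = [(s, [s])]
            while stack:  # enumerate every path of exactly shortest length
                u, path = stack.pop()
                if u == t:
                    paths.append(path)
                    continue
                if len(path) - 1 >= dist[t]:
                    continue
                for v in adj.get(u, ()):
                    if v not in path:
                        stack.append((v, path + [v]))
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1.0 / len(paths)
    return score


def neumann_total_relation(x, terms):
    """sum_{k=1..terms} X^k — exact T for nilpotent (acyclic) X."""
    total = np.zeros_like(x)
    power = np.eye(x.shape[0])
    for _ in range(terms):
        power = power @ x
        total += power
    return total


# ---------------------------------------------------------------------------
# degree


class TestDegree:
    def test_chain_degrees(self):
        scores = rank(diagram_from_edges([("a", "b", 1), ("b", "c", 1)]), "degree").scores
        assert scores == {"a": 1, "b": 2, "c": 1}

    def test_isolated_variable_scores_zero(self):
        d = diagram_from_edges([("a", "b", 1)], extra_vars=["z"])
        assert rank(d, "degree").scores["z"] == 0

    @given(small_diagrams(max_nodes=10))
    def test_handshake_identity(self, d):
        assert sum(rank(d, "degree").scores.values()) == 2 * d.n_edges


# ---------------------------------------------------------------------------
# betweenness


class TestBetweenness:
    def test_middle_of_chain(self):
        scores = rank(
            diagram_from_edges([("a", "b", 1), ("b", "c", 1)]), "betweenness"
        ).scores
        assert scores == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_complete_digraph_has_no_intermediaries(self):
        edges = [(s, t, 1) for s in "abc" for t in "abc" if s != t]
        assert set(rank(diagram_from_edges(edges), "betweenness").scores.values()) == {0.0}

    def test_matches_exhaustive_path_oracle_on_random_digraphs(self, rng):
        for _ in range(40):
            d = random_digraph(rng, int(rng.integers(3, 9)), p=0.3)
            got = rank(d, "betweenness").scores
            expected = brute_betweenness(d)
            for v in expected:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)


# ---------------------------------------------------------------------------
# closeness (directed harmonic)


class TestCloseness:
    def test_chain_scores(self):
        scores = rank(
            diagram_from_edges([("a", "b", 1), ("b", "c", 1)]), "closeness"
        ).scores
        assert scores["a"] == pytest.approx(1.5)  # 1/1 + 1/2
        assert scores["c"] == 0.0

    def test_isolated_node_scores_zero(self):
        d = diagram_from_edges([], extra_vars=["solo"])
        assert rank(d, "closeness").scores == {"solo": 0.0}

    @pytest.mark.parametrize("n", [3, 5])
    def test_complete_digraph_scores_n_minus_1(self, n):
        ids = [f"v{i}" for i in range(n)]
        edges = [(s, t, 1) for s in ids for t in ids if s != t]
        assert set(rank(diagram_from_edges(edges), "closeness").scores.values()) == {
            float(n - 1)
        }

    def test_matches_bfs_oracle_on_random_digraphs(self, rng):
        for _ in range(20):
            d = random_digraph(rng, 7, p=0.25)
            got = rank(d, "closeness").scores
            for v in d.variables:
                dist = bfs_distances(d, v)
                expected = sum(1.0 / k for u, k in dist.items() if u != v)
                assert got[v] == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# eigenvector centrality (undirected projection)


class TestEigencentrality:
    def test_star_hub_is_maximal(self):
        d = diagram_from_edges([("hub", "l1", 1), ("hub", "l2", 1), ("l3", "hub", 1)])
        scores = rank(d, "eigencentrality").scores
        assert scores["hub"] == pytest.approx(1.0)
        assert all(scores[v] < 1.0 for v in ("l1", "l2", "l3"))

    def test_cycle_of_four_is_uniform(self):
        d = diagram_from_edges(
            [("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "a", 1)]
        )
        scores = rank(d, "eigencentrality").scores
        assert all(s == pytest.approx(1.0, abs=1e-6) for s in scores.values())

    def test_two_disjoint_edges_match_power_iteration_oracle(self):
        d = diagram_from_edges([("a", "b", 1), ("c", "d", 1)])
        scores = rank(d, "eigencentrality").scores
        # oracle: power iteration from a uniform start on the 4x4 projection
        a = np.array(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=float
        )
        v = np.ones(4) / 2
        for _ in range(200):
            v = a @ v
            v /= np.linalg.norm(v)
        v /= v.max()
        for vid, expected in zip("abcd", v):
            assert scores[vid] == pytest.approx(expected, abs=1e-6)

    def test_edgeless_diagram_scores_zero(self):
        d = diagram_from_edges([], extra_vars=["a", "b"])
        assert set(rank(d, "eigencentrality").scores.values()) == {0.0}


# ---------------------------------------------------------------------------
# DEMATEL


class TestDematel:
    def test_single_edge_nilpotent_case(self):
        res = dematel(diagram_from_edges([("a", "b", 1)]))
        assert res.T.tolist() == [[0, 1], [0, 0]]
        assert res.D.tolist() == [1, 0]
        assert res.R.tolist() == [0, 1]
        assert res.prominence.tolist() == [1, 1]
        assert res.relation.tolist() == [1, -1]

    def test_three_chain_accumulates_indirect_influence(self):
        res = dematel(diagram_from_edges([("a", "b", 1), ("b", "c", 1)]))
        # s = 1, X nilpotent: T = X + X^2 exactly
        assert res.T.tolist() == [[0, 1, 1], [0, 0, 1], [0, 0, 0]]
        assert res.prominence.tolist() == [2, 2, 2]
        assert res.relation.tolist() == [2, 0, -2]

    def test_empty_diagram_scores_zero(self):
        res = dematel(diagram_from_edges([], extra_vars=["a", "b", "c"]))
        assert res.s == 0.0
        assert not res.T.any()
        assert not res.prominence.any()

    def test_polarity_is_ignored_by_the_analysis(self):
        pos = dematel(diagram_from_edges([("a", "b", 1), ("b", "c", 1)]))
        mixed = dematel(diagram_from_edges([("a", "b", -1), ("b", "c", 1)]))
        assert np.array_equal(pos.T, mixed.T)

    def test_acyclic_matches_truncated_neumann_series(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            d = diagram_from_edges(
                [
                    (f"v{i}", f"v{j}", 1)
                    for i in range(n)
                    for j in range(i + 1, n)
                    if rng.random() < 0.4
                ],
                extra_vars=[f"v{i}" for i in range(n)],
            )
            res = dematel(d)
            assert np.allclose(
                res.T, neumann_total_relation(res.X, d.n_variables), atol=1e-12
            )

    def test_dispatch_and_receive_balance(self, rng):
        for _ in range(20):
            d = random_digraph(rng, int(rng.integers(3, 10)), p=0.35)
            res = dematel(d)
            assert res.D.sum() == pytest.approx(res.R.sum(), abs=1e-9)
            assert res.D.sum() == pytest.approx(res.T.sum(), abs=1e-9)
            assert np.all(res.prominence >= np.abs(res.relation) - 1e-12)
            assert np.all(res.T >= -1e-12)

    def test_transpose_duality(self, rng):
        d = random_digraph(rng, 7, p=0.3)
        transposed = diagram_from_edges(
            [(e.target, e.source, e.polarity) for e in d.sorted_edges()],
            extra_vars=list(d.variables),
        )
        res, res_t = dematel(d), dematel(transposed)
        assert np.allclose(res.D, res_t.R, atol=1e-9)
        assert np.allclose(res.R, res_t.D, atol=1e-9)
        assert np.allclose(res.prominence, res_t.prominence, atol=1e-9)
        assert np.allclose(res.relation, -res_t.relation, atol=1e-9)

    def test_two_cycle_needs_and_survives_epsilon_rescale(self):
        d = diagram_from_edges([("a", "b", 1), ("b", "a", 1)])
        with pytest.warns(UserWarning, match="singular"):
            res = dematel(d)
        assert res.s > 1.0
        assert np.all(np.isfinite(res.T))

    def test_ranking_is_by_prominence_descending(self):
        d = diagram_from_edges([("a", "b", 1), ("b", "c", 1)])
        result = dematel(d).ranking()
        assert result.ordering == ("a", "b", "c")  # tie broken by id


class TestClusterCutpoint:
    @staticmethod
    def _result_with_prominence(values):
        """Build a DEMATELResult carrying a given prominence profile."""
        from cldsynth.ranking import DEMATELResult

        n = len(values)
        zeros = np.zeros((n, n))
        prom = np.array(values, dtype=float)
        return DEMATELResult(
            ordering=tuple(f"v{i}" for i in range(n)),
            A=zeros, s=1.0, X=zeros, T=zeros,
            D=prom / 2, R=prom / 2, prominence=prom, relation=np.zeros(n),
        )

    def test_forced_gap_position(self):
        res = self._result_with_prominence([10, 9, 8, 1, 0.5])
        assert find_cluster_cutpoint(res, max_k=4) == 3

    def test_flat_profile_signals_no_cluster(self):
        res = self._result_with_prominence([5, 5, 5, 5])
        with pytest.raises(NoClusterError):
            find_cluster_cutpoint(res)

    def test_recovers_planted_gap(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 20))
            k = int(rng.integers(2, min(15, n - 1) + 1))
            high = np.sort(rng.uniform(10, 11, size=k))[::-1]
            low = np.sort(rng.uniform(0, 1, size=n - k))[::-1]
            res = self._result_with_prominence(list(high) + list(low))
            assert find_cluster_cutpoint(res) == k

    def test_max_k_out_of_range_rejected(self):
        res = self._result_with_prominence([3, 2, 1])
        with pytest.raises(CldError, match="max_k"):
            find_cluster_cutpoint(res, max_k=5)


class TestDispatch:
    @pytest.mark.parametrize("technique", TECHNIQUES)
    def test_every_technique_scores_every_variable(self, technique, rng):
        d = random_digraph(rng, 9, p=0.25)
        result = rank(d, technique)
        assert set(result.scores) == set(d.variables)
        assert sorted(result.ordering) == sorted(d.variables)

    def test_unknown_technique_rejected(self):
        with pytest.raises(CldError, match="unknown technique"):
            rank(diagram_from_edges([("a", "b", 1)]), "pagerank")
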