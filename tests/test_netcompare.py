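"""Walktrap communities (checked against exhaustive modularity
maximisation and an independent reference implementation) and partition
agreement metrics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from larvaconnect import ConnectivityMatrix, build_graph, partition_agreement, walktrap_communities
from larvaconnect.netcompare import CommunityPartition, partition_modularity, site_partition_from_individuals

WINDOW = ("2021-02-01", "2021-02-08")


def set_partitions(items):
    """All partitions of a small set (restricted-growth strings)."""
    items = list(items)
    n = len(items)

    def rec(i, groups):
        if i == n:
            yield [list(g) for g in groups]
            return
        for g in groups:
            g.append(items[i])
            yield from rec(i + 1, groups)
            g.pop()
        groups.append([items[i]])
        yield from rec(i + 1, groups)
        groups.pop()

    yield from rec(0, [])


def exhaustive_best_modularity(G):
    nodes = sorted(G.nodes)
    W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    best, best_part = -np.inf, None
    for part in set_partitions(range(len(nodes))):
        labels = np.empty(len(nodes), dtype=int)
        for c, group in enumerate(part):
            labels[group] = c
        q = partition_modularity(W, labels)
        if q > best:
            best, best_part = q, labels.copy()
    return best, best_part


def two_cliques():
    G = nx.Graph()
    for base in (0, 5):
        for i, j in itertools.combinations(range(5), 2):
            G.add_edge(base + i, base + j, weight=1.0)
    G.add_edge(4, 5, weight=1.0)
    return G


class TestBuildGraph:
    def test_symmetrised_edge_weight(self):
        C = ConnectivityMatrix(["a", "b"], np.array([[0, 3], [2, 0]]), WINDOW)
        G = build_graph(C)
        assert G["a"]["b"]["weight"] == 5 and G.number_of_edges() == 1

    def test_min_count_drops_all(self):
        C = ConnectivityMatrix(["a", "b"], np.array([[0, 3], [2, 0]]), WINDOW)
        G = build_graph(C, min_count=6)
        assert G.number_of_edges() == 0 and G.number_of_nodes() == 2

    def test_diagonal_never_becomes_edge(self):
        C = ConnectivityMatrix(["a", "b"], np.array([[9, 1], [1, 9]]), WINDOW)
        G = build_graph(C)
        assert not any(u == v for u, v in G.edges)


class TestWalktrap:
    def test_two_cliques_recovered_and_match_exhaustive_optimum(self):
        G = two_cliques()
        part = walktrap_communities(G)
        assert part.n_communities == 2
        # the two cliques exactly
        labs = part.labels
        assert len({labs[i] for i in range(5)}) == 1
        assert len({labs[i] for i in range(5, 10)}) == 1
        best_q, best_labels = exhaustive_best_modularity(G)
        assert part.score == pytest.approx(best_q, abs=1e-12)

    def test_complete_graph_single_community(self):
        G = nx.complete_graph(6)
        nx.set_edge_attributes(G, 1.0, "weight")
        assert walktrap_communities(G).n_communities == 1

    def test_planted_partition_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        n_blocks, per = 4, 20
        G = nx.Graph()
        G.add_nodes_from(range(n_blocks * per))
        for i in range(n_blocks * per):
            for j in range(i + 1, n_blocks * per):
                p = 0.3 if i // per == j // per else 0.02
                if rng.random() < p:
                    G.add_edge(i, j, weight=1.0)
        mine = walktrap_communities(G, steps=4)
        truth = np.repeat(np.arange(n_blocks), per)
        assert partition_agreement(
            mine, CommunityPartition(sorted(G.nodes), truth, method="reference")
        ).ari == 1.0

        igraph = pytest.importorskip("igraph")
        g = igraph.Graph.from_networkx(G)
        ref = np.array(g.community_walktrap(steps=4).as_clustering().membership)
        order = list(g.vs["_nx_name"])
        ref_sorted = ref[np.argsort(order)]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(mine.labels, ref_sorted) == 1.0

    def test_zero_weight_graph_all_singletons(self):
        G = nx.empty_graph(4)
        part = walktrap_communities(G)
        assert part.n_communities == 4

    def test_partition_beats_trivial_partitions(self):
        G = two_cliques()
        W = nx.to_numpy_array(G, nodelist=sorted(G.nodes), weight="weight")
        part = walktrap_communities(G)
        singletons = partition_modularity(W, np.arange(10))
        one = partition_modularity(W, np.zeros(10, dtype=int))
        assert part.score >= singletons and part.score >= one

    def test_node_permutation_invariance(self):
        G = two_cliques()
        H = nx.relabel_nodes(G, {i: 9 - i for i in range(10)})
        p1 = walktrap_communities(G)
        p2 = walktrap_communities(H)
        # compare as partitions of the same underlying nodes
        remap = CommunityPartition([9 - n for n in p2.nodes], p2.labels, method="walktrap")
        order = np.argsort(remap.nodes)
        aligned = CommunityPartition(
            [remap.nodes[i] for i in order],
            np.array([remap.labels[i] for i in order]),
            method="walktrap",
        )
        assert partition_agreement(p1, aligned).ari == 1.0

    def test_fixed_k_cut(self):
        G = two_cliques()
        part = walktrap_communities(G, n_communities=3)
        assert part.n_communities == 3


class TestAgreement:
    def test_identical_partitions_perfect(self):
        p = CommunityPartition(list("abcd"), np.array([0, 0, 1, 1]))
        assert partition_agreement(p, p).ari == 1.0
        assert partition_agreement(p, p).nmi == 1.0

    def test_singletons_vs_one_cluster_ari_zero(self):
        p1 = CommunityPartition(list("abcd"), np.arange(4))
        p2 = CommunityPartition(list("abcd"), np.zeros(4, dtype=int))
        assert partition_agreement(p1, p2).ari == 0.0

    def test_random_partitions_centre_on_zero(self):
        rng = np.random.default_rng(1)
        nodes = list(range(100))
        aris = []
        for _ in range(50):
            p1 = CommunityPartition(nodes, rng.integers(0, 4, 100), method="a")
            p2 = CommunityPartition(nodes, rng.integers(0, 4, 100), method="b")
            # labels from integers may skip values; normalise
            aris.append(
                partition_agreement(
                    CommunityPartition(nodes, _canon(p1.labels), "a"),
                    CommunityPartition(nodes, _canon(p2.labels), "b"),
                ).ari
            )
        assert abs(np.mean(aris)) < 0.05

    def test_node_set_mismatch_rejected(self):
        p1 = CommunityPartition(list("abc"), np.zeros(3, dtype=int))
        p2 = CommunityPartition(list("abd"), np.zeros(3, dtype=int))
        with pytest.raises(ValueError):
            partition_agreement(p1, p2)

    def test_majority_vote_site_projection(self):
        import pandas as pd

        labels = pd.Series([0, 0, 1, 1, 1, 0], index=[f"i{k}" for k in range(6)])
        sites = pd.Series(["A", "A", "A", "B", "B", "B"], index=labels.index)
        part = site_partition_from_individuals(labels, sites, ["A", "B"])
        assert part.labels.tolist() == [0, 1]


def _canon(labels):
    seen = {}
    out = np.empty_like(labels)
    for i, v in enumerate(labels):
        out[i] = seen.setdefault(v, len(seen))
    return out
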