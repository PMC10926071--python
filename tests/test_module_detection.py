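import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netmarker.coexpr_network import CorrelationMatrix
from netmarker.module_detection import (
    ModulePartition,
    gap_statistic,
    gene_distance,
    kmeans_modules,
    louvain,
    modularity,
    profile_embedding,
)


def partition_from_labels(nodes, labels):
    groups = {}
    for n, l in zip(nodes, labels):
        groups.setdefault(l, []).append(n)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    assign = {}
    for i, grp in enumerate(ordered, start=1):
        for n in grp:
            assign[n] = i
    return ModulePartition(pd.Series(assign))


def modularity_oracle(net, labels):
    """Brute-force evaluation over all ordered node pairs."""
    nodes = list(net.nodes)
    a = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    two_w = a.sum()
    k = a.sum(1)
    s = 0.0
    for i in range(len(nodes)):
        for j in range(len(nodes)):
            if labels[nodes[i]] == labels[nodes[j]]:
                s += a[i, j] - k[i] * k[j] / two_w
    return s / two_w


def all_partitions(items):
    """Every set partition (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def two_triangles():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], weight=1.0)
    return g


class TestGeneDistance:
    def test_one_minus_correlation(self):
        c = pd.DataFrame([[1.0, 1.0, 0.0], [1.0, 1.0, 0.5], [0.0, 0.5, 1.0]],
                         index=list("abc"), columns=list("abc"))
        d = gene_distance(CorrelationMatrix(C=c))
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0
        assert d.loc["b", "c"] == 0.5
        assert (np.diag(d) == 0).all()


class TestKmeansModules:
    def test_two_separated_clouds_recovered(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(10, 0.1, (12, 3))])
        feats = pd.DataFrame(x, index=[f"g{i:02d}" for i in range(22)])
        part = kmeans_modules(feats, 2, seed=1)
        # oracle: nearest true center
        truth = np.array([0] * 10 + [1] * 12)
        labels = part.assignments.reindex(feats.index).to_numpy()
        assert len(set(zip(truth, labels))) == 2

    def test_k_one_single_module(self):
        feats = pd.DataFrame(np.random.default_rng(1).normal(size=(8, 2)))
        part = kmeans_modules(feats, 1, seed=0)
        assert part.k == 1

    def test_deterministic_given_seed(self):
        feats = pd.DataFrame(np.random.default_rng(2).normal(size=(30, 4)))
        p1 = kmeans_modules(feats, 3, seed=7)
        p2 = kmeans_modules(feats, 3, seed=7)
        pd.testing.assert_series_equal(p1.assignments, p2.assignments)

    def test_identical_points_deterministic(self):
        feats = pd.DataFrame(np.ones((6, 2)), index=list("abcdef"))
        part = kmeans_modules(feats, 2, seed=0)
        assert part.assignments.notna().all()

    def test_module_ids_contiguous_from_one(self):
        with pytest.raises(ValueError, match="contiguous"):
            ModulePartition(pd.Series({"a": 1, "b": 3}))


class TestGapStatistic:
    def test_five_blobs_selects_five(self):
        hits = 0
        centers = np.array(
            [[np.cos(t), np.sin(t)] for t in np.linspace(0, 2 * np.pi, 6)[:-1]]
        ) * 10.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.vstack([c + rng.normal(0, 0.5, (10, 2)) for c in centers])
            feats = pd.DataFrame(pts)
            k, _ = gap_statistic(feats, k_range=range(1, 11), b=20, seed=seed)
            hits += k == 5
        assert hits >= 18

    def test_single_blob_selects_one(self):
        rng = np.random.default_rng(11)
        feats = pd.DataFrame(rng.normal(0, 1, size=(60, 2)))
        k, _ = gap_statistic(feats, k_range=range(1, 8), b=20, seed=5)
        assert k == 1

    def test_reference_count_floor(self):
        feats = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError, match="10 reference"):
            gap_statistic(feats, b=5)


class TestModularity:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_in_one_partition_scores_zero(self, seed):
        g = nx.gnp_random_graph(10, 0.4, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = partition_from_labels(g.nodes, [1] * g.number_of_nodes())
        assert modularity(g, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles_score_half(self):
        g = two_triangles()
        part = partition_from_labels(g.nodes, [1, 1, 1, 2, 2, 2])
        assert modularity(g, part) == pytest.approx(0.5)

    def test_singletons_closed_form(self):
        g = nx.path_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = partition_from_labels(g.nodes, list(range(5)))
        k = np.array([d for _, d in g.degree()], dtype=float)
        expected = -(k**2).sum() / (2 * g.number_of_edges()) ** 2
        assert modularity(g, part) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_ordered_pair_oracle_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(7, 0.5, seed=seed)
        if g.number_of_edges() == 0:
            g.add_edge(0, 1)
        for _, _, d in g.edges(data=True):
            d["weight"] = float(rng.uniform(0.1, 1.0))
        labels = {n: int(rng.integers(0, 3)) for n in g.nodes}
        part = partition_from_labels(g.nodes, [labels[n] for n in g.nodes])
        relabeled = {n: part.assignments[n] for n in g.nodes}
        assert modularity(g, part) == pytest.approx(modularity_oracle(g, relabeled))


class TestLouvain:
    def test_recovers_two_triangles(self):
        part, score = louvain(two_triangles(), seed=0)
        assert part.k == 2
        assert score == pytest.approx(0.5)
        assert part.assignments[0] == part.assignments[1] == part.assignments[2]

    def test_star_stays_one_community(self):
        g = nx.star_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        part, score = louvain(g, seed=0)
        # exhaustive check: no split of a star improves on all-in-one
        best = max(
            modularity(g, partition_from_labels(list(g.nodes), labels))
            for labels in itertools.product(range(2), repeat=6)
        )
        assert best <= 0 + 1e-12
        assert part.k == 1
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_never_below_all_in_one_baseline(self):
        for seed in range(5):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            if g.number_of_edges() == 0:
                continue
            nx.set_edge_attributes(g, 1.0, "weight")
            _, score = louvain(g, seed=seed)
            assert score >= -1e-12

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        p1, s1 = louvain(g, seed=42)
        p2, s2 = louvain(g, seed=42)
        assert s1 == s2
        pd.testing.assert_series_equal(p1.assignments, p2.assignments)


class TestProfileEmbedding:
    def test_preserves_cluster_separation(self):
        rng = np.random.default_rng(0)
        block = np.kron(np.eye(3), np.ones((5, 5))) * 0.8 + 0.1
        noise = rng.normal(0, 0.02, size=(15, 15))
        c = np.clip(block + noise + noise.T, 0, 1)
        np.fill_diagonal(c, 1.0)
        feats = pd.DataFrame(c, index=[f"g{i}" for i in range(15)])
        emb = profile_embedding(feats, var_explained=0.9)
        assert emb.shape[0] == 15
        assert emb.shape[1] <= 15
        part = kmeans_modules(emb, 3, seed=0)
        truth = np.repeat([0, 1, 2], 5)
        labels = part.assignments.reindex(feats.index).to_numpy()
        assert len(set(zip(truth, labels))) == 3
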