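"""Mining: similarity search, clustering, networks, gene-set enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from oracles import hypergeom_tail_oracle, naive_agglomerate, two_block_matrix

from shmkit.errors import ValidationError
from shmkit.mining import (
    Dendrogram,
    adjacency,
    cut_tree,
    detect_modules,
    hcluster,
    hypergeom_enrich,
    read_gmt,
    similarity_search,
    write_graphml,
)


def _rand_matrix(n, m, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, m)),
        index=[f"g{i:03d}" for i in range(n)],
        columns=[f"s{j}" for j in range(m)],
    )


class TestSimilaritySearch:
    def test_exact_copy_ranks_first(self):
        vals = _rand_matrix(20, 8, 1)
        vals.loc["g_copy"] = vals.loc["g000"]
        got = similarity_search(vals, "g000", top_n=2)
        assert got == ["g000", "g_copy"]

    def test_top_pct_count_rule(self):
        vals = _rand_matrix(200, 8, 2)
        got = similarity_search(vals, "g000", top_pct=15)
        assert len(got) == math.ceil(0.15 * 200) == 30
        assert got[0] == "g000"

    @pytest.mark.parametrize("metric", ["pearson", "spearman", "euclidean"])
    def test_ranking_matches_brute_force(self, metric):
        from scipy.stats import pearsonr, spearmanr

        vals = _rand_matrix(50, 8, 3)
        got = similarity_search(vals, "g010", metric=metric, top_n=50)
        q = vals.loc["g010"].to_numpy()

        def score(g):
            v = vals.loc[g].to_numpy()
            if metric == "pearson":
                return -pearsonr(q, v).statistic
            if metric == "spearman":
                return -spearmanr(q, v).statistic
            return float(np.sqrt(((q - v) ** 2).sum()))

        expect = ["g010"] + sorted(
            (g for g in vals.index if g != "g010"), key=lambda g: (score(g), g)
        )
        assert got == expect

    def test_selector_validation(self):
        vals = _rand_matrix(10, 5, 4)
        with pytest.raises(ValidationError):
            similarity_search(vals, "g000")
        with pytest.raises(ValidationError):
            similarity_search(vals, "g000", top_n=3, top_pct=10)
        with pytest.raises(ValidationError):
            similarity_search(vals, "g000", top_pct=0)
        with pytest.raises(ValidationError):
            similarity_search(vals, "nope", top_n=3)


class TestHcluster:
    def test_three_points_on_line(self):
        vals = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("abc"))
        dend = hcluster(vals, distance="euclidean", linkage="average")
        assert dend.merges[0] == (0, 1)
        assert dend.heights[0] == pytest.approx(1.0)

    def test_duplicated_rows_merge_at_zero_first(self):
        vals = pd.DataFrame(
            [[1.0, 2.0], [5.0, 9.0], [1.0, 2.0]], index=list("abc")
        )
        dend = hcluster(vals, distance="euclidean")
        assert dend.heights[0] == pytest.approx(0.0)
        assert dend.merges[0] == (0, 2)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    @pytest.mark.parametrize("distance", ["euclidean", "correlation"])
    def test_heights_match_naive_oracle(self, linkage, distance):
        vals = _rand_matrix(12, 6, 17)
        from shmkit.mining import _pairwise_distance

        D = _pairwise_distance(vals.to_numpy(), distance, list(vals.index))
        dend = hcluster(vals, distance=distance, linkage=linkage)
        expect = naive_agglomerate(D, linkage)
        assert np.allclose(dend.heights, expect, atol=1e-10)

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    def test_heights_match_scipy(self, linkage):
        """Independent cross-check against scipy's linkage implementation."""
        from scipy.cluster.hierarchy import linkage as scipy_linkage
        from scipy.spatial.distance import pdist

        vals = _rand_matrix(15, 5, 23)
        dend = hcluster(vals, distance="euclidean", linkage=linkage)
        Z = scipy_linkage(pdist(vals.to_numpy()), method=linkage)
        assert np.allclose(sorted(dend.heights), sorted(Z[:, 2]), atol=1e-10)

    def test_heights_nondecreasing(self):
        vals = _rand_matrix(20, 6, 31)
        for linkage in ("average", "complete", "single"):
            dend = hcluster(vals, distance="correlation", linkage=linkage)
            assert all(
                b >= a - 1e-12 for a, b in zip(dend.heights, dend.heights[1:])
            )

    def test_constant_row_under_correlation_named(self):
        vals = _rand_matrix(5, 6, 5)
        vals.loc["g002"] = 3.0
        with pytest.raises(ValidationError, match="g002"):
            hcluster(vals, distance="correlation")

    def test_leaf_order_is_valid(self):
        vals = _rand_matrix(10, 6, 7)
        dend = hcluster(vals, distance="euclidean")
        order = dend.leaf_order()
        assert sorted(order) == sorted(dend.labels)


class TestCutTree:
    @pytest.fixture()
    def dend(self):
        return hcluster(_rand_matrix(10, 6, 11), distance="euclidean")

    def test_above_root_single_cluster(self, dend):
        labels = cut_tree(dend, h=max(dend.heights) + 1)
        assert set(labels.values()) == {1}

    def test_k_equals_n_singletons(self, dend):
        labels = cut_tree(dend, k=10)
        assert sorted(labels.values()) == list(range(1, 11))

    def test_recovers_planted_blocks(self):
        rng = np.random.default_rng(13)
        block1 = rng.normal(0, 1, size=8) + rng.normal(0, 0.1, size=(10, 8))
        block2 = rng.normal(0, 1, size=8) + rng.normal(0, 0.1, size=(10, 8))
        vals = pd.DataFrame(
            np.vstack([block1, block2]),
            index=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
        )
        dend = hcluster(vals, distance="correlation")
        labels = cut_tree(dend, k=2)
        la = {labels[f"a{i}"] for i in range(10)}
        lb = {labels[f"b{i}"] for i in range(10)}
        assert len(la) == 1 and len(lb) == 1 and la != lb

    def test_argument_validation(self, dend):
        with pytest.raises(ValidationError):
            cut_tree(dend)
        with pytest.raises(ValidationError):
            cut_tree(dend, h=1.0, k=2)
        with pytest.raises(ValidationError):
            cut_tree(dend, k=11)


class TestAdjacency:
    def test_identical_rows_beta1(self):
        vals = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]], index=["a", "b"])
        g = adjacency(vals, beta=1)
        assert g.adjacency[0, 1] == pytest.approx(1.0)

    def test_power_sharpening(self):
        assert 0.5**6 == pytest.approx(0.015625)
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.normal(size=(20, 6)))
        cor = np.corrcoef(vals.to_numpy())
        g = adjacency(vals, beta=6)
        assert np.allclose(g.adjacency - np.eye(20), np.abs(cor) ** 6 - np.eye(20))

    def test_symmetric_unit_diagonal(self):
        vals = _rand_matrix(15, 7, 19)
        g = adjacency(vals, beta=6)
        assert np.allclose(g.adjacency, g.adjacency.T)
        assert np.allclose(np.diag(g.adjacency), 1.0)
        assert g.adjacency.min() >= 0 and g.adjacency.max() <= 1

    def test_constant_row_rejected(self):
        vals = _rand_matrix(4, 5, 2)
        vals.iloc[1] = 7.0
        with pytest.raises(ValidationError):
            adjacency(vals)


_two_block_matrix = two_block_matrix


class TestModules:
    def test_two_planted_blocks_recovered(self):
        vals = _two_block_matrix()
        g = detect_modules(adjacency(vals, beta=6), min_size=5, cut_height=0.8)
        lab = dict(zip(g.genes, g.module_labels))
        m1 = {lab[f"m1_{i}"] for i in range(10)}
        m2 = {lab[f"m2_{i}"] for i in range(10)}
        assert len(m1) == 1 and len(m2) == 1 and m1 != m2
        assert 0 not in m1 | m2

    def test_min_size_larger_than_n_unassigns_all(self):
        vals = _two_block_matrix()
        g = detect_modules(adjacency(vals), min_size=50, cut_height=0.8)
        assert (g.module_labels == 0).all()
        assert np.allclose(g.connectivity, 0.0)

    def test_connectivity_three_gene_module(self):
        from shmkit.mining import ModuleGraph

        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        g = ModuleGraph(genes=["x", "y", "z"], adjacency=a, beta=6)
        out = detect_modules(g, min_size=2, cut_height=0.9)
        assert np.allclose(out.connectivity, 1.0)

    def test_labels_invariant_under_row_permutation(self):
        vals = _two_block_matrix()
        g1 = detect_modules(adjacency(vals, beta=6), min_size=5, cut_height=0.8)
        perm = vals.sample(frac=1.0, random_state=4)
        g2 = detect_modules(adjacency(perm, beta=6), min_size=5, cut_height=0.8)
        lab1 = dict(zip(g1.genes, g1.module_labels))
        lab2 = dict(zip(g2.genes, g2.module_labels))
        # same partition up to label renaming
        from collections import defaultdict

        p1, p2 = defaultdict(set), defaultdict(set)
        for g, l in lab1.items():
            p1[l].add(g)
        for g, l in lab2.items():
            p2[l].add(g)
        assert sorted(map(sorted, p1.values())) == sorted(map(sorted, p2.values()))

    def test_min_size_validation(self):
        vals = _two_block_matrix()
        with pytest.raises(ValidationError):
            detect_modules(adjacency(vals), min_size=1)

    def test_graphml_export(self, tmp_path):
        import networkx as nx

        vals = _two_block_matrix()
        g = detect_modules(adjacency(vals, beta=6), min_size=5, cut_height=0.8)
        p = tmp_path / "net.graphml"
        write_graphml(g, p, edge_threshold=0.1)
        G = nx.read_graphml(p)
        assert set(G.nodes) == set(g.genes)
        assert all(d["adjacency"] >= 0.1 for _, _, d in G.edges(data=True))
        some = next(iter(G.nodes(data=True)))[1]
        assert {"module", "connectivity"} <= set(some)


class TestHypergeom:
    def test_cluster_equals_universe(self):
        u = {f"g{i}" for i in range(10)}
        tab = hypergeom_enrich(u, {"s": set(u)}, u)
        assert tab["p"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_extreme(self):
        u = {f"g{i}" for i in range(20)}
        s = {f"g{i}" for i in range(5)}
        tab = hypergeom_enrich(s, {"s": s}, u)
        assert tab["p"].iloc[0] == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_tail_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        universe = {f"g{i}" for i in range(40)}
        ulist = sorted(universe)
        for _ in range(50):
            s = set(rng.choice(ulist, size=rng.integers(2, 20), replace=False))
            c = set(rng.choice(ulist, size=rng.integers(2, 20), replace=False))
            tab = hypergeom_enrich(c, {"s": s}, universe)
            expect = hypergeom_tail_oracle(40, len(s), len(c), len(c & s))
            assert tab["p"].iloc[0] == pytest.approx(expect, rel=1e-9, abs=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrich(set(), {"s": {"a"}}, set())

    def test_gmt_roundtrip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("pathA\tdesc\tg1\tg2\ng3\npathB\tdesc\tg2\t\n")
        sets = read_gmt(p)
        assert sets == {"pathA": {"g1", "g2"}, "pathB": {"g2"}}
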