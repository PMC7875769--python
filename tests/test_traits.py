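"""Tissue-trait aggregation, permutation null, cross-trait networks."""

import math

import numpy as np
import pandas as pd
import pytest

from enhancerkit import gwas as gw
from enhancerkit import traits as tr


def tree_from(frame):
    return gw.build_tree(frame)


def md(samples, groups):
    return pd.DataFrame({"sample": samples, "tissue_group": groups})


class TestAssignNodeTissues:
    def _tree(self):
        frame = pd.DataFrame(
            np.eye(4, dtype=int) + np.ones((4, 4), dtype=int),
            index=list("abcd"), columns=["s0", "s1", "s2", "s3"]).clip(upper=1)
        return tree_from(frame)

    def test_strict_majority_and_leaf_labels(self):
        tree = self._tree()
        labels = tr.assign_node_tissues(
            tree, md(["s0", "s1", "s2", "s3"], ["heart", "heart", "heart", "lung"]))
        for i in tree.leaves():
            (leaf,) = tree.nodes[i].leaves
            assert labels[i] == {"s3": "lung"}.get(leaf, "heart")
        assert labels[tree.root] == "heart"  # 3 of 4 leaves

    def test_even_split_is_multiple(self):
        frame = pd.DataFrame([[1, 1], [0, 1]], index=["e0", "e1"],
                             columns=["s0", "s1"])
        tree = tree_from(frame)
        labels = tr.assign_node_tissues(tree, md(["s0", "s1"], ["heart", "lung"]))
        assert labels[tree.root] == "multiple"

    def test_missing_metadata_raises(self):
        tree = self._tree()
        with pytest.raises(ValueError, match="without metadata"):
            tr.assign_node_tissues(tree, md(["s0"], ["heart"]))


def enrichment_rows(rows):
    df = pd.DataFrame(rows, columns=["node", "trait", "p_hyper", "significant"])
    return df


class TestTissueTraitMatrix:
    labels = pd.Series({0: "heart", 1: "heart", 2: "lung"})

    def test_neglogp_sums_per_tissue(self):
        table = enrichment_rows([(0, "t", 1e-3, True), (1, "t", 1e-2, True),
                                 (2, "t", 1e-4, True)])
        mat = tr.tissue_trait_matrix(table, self.labels)
        assert mat.loc["heart", "t"] == pytest.approx(5.0)
        assert mat.loc["lung", "t"] == pytest.approx(4.0)

    def test_insignificant_nodes_excluded(self):
        table = enrichment_rows([(0, "t", 1e-3, False)])
        mat = tr.tissue_trait_matrix(table, self.labels)
        assert (mat["t"] == 0).all()

    def test_normalized_columns_sum_to_one(self):
        table = enrichment_rows([(0, "t", 1e-3, True), (2, "t", 1e-4, True),
                                 (0, "u", 0.5, False)])
        mat = tr.tissue_trait_matrix(table, self.labels, normalize=True)
        assert mat["t"].sum() == pytest.approx(1.0)
        assert mat["u"].sum() == 0.0


class TestClassifyTraits:
    def test_threshold_rules(self):
        mat = pd.DataFrame({
            "uni": [1] + [0] * 11,
            "multi": [1] * 7 + [0] * 5,
            "poly": [1] * 12,
        }, index=[f"g{i}" for i in range(12)])
        out = tr.classify_traits(mat).set_index("trait")
        assert out.loc["uni", "class"] == "unifactorial"
        assert out.loc["multi", "class"] == "multifactorial"
        assert not out.loc["multi", "polyfactorial"]
        assert out.loc["poly", "polyfactorial"]

    def test_empty_trait_excluded_with_warning(self):
        mat = pd.DataFrame({"a": [1, 0], "none": [0, 0]}, index=["g0", "g1"])
        with pytest.warns(UserWarning, match="excluded"):
            out = tr.classify_traits(mat)
        assert "none" not in set(out["trait"])


class TestTissueSimilarity:
    def test_jaccard_of_rows(self):
        mat = pd.DataFrame({"t1": [1, 0], "t2": [1, 1], "t3": [1, 1], "t4": [0, 1]},
                           index=["a", "b"])
        sim = tr.tissue_similarity(mat)
        assert sim.loc["a", "b"] == pytest.approx(2 / 4)
        assert sim.loc["a", "a"] == 1.0

    def test_disjoint_rows_are_zero(self):
        mat = pd.DataFrame({"t1": [1, 0], "t2": [0, 1]}, index=["a", "b"])
        assert tr.tissue_similarity(mat).loc["a", "b"] == 0.0


class TestPermutationNull:
    def _labels(self, n_a, n_b, n_c):
        idx = [f"n{i}" for i in range(n_a + n_b + n_c)]
        lab = ["A"] * n_a + ["B"] * n_b + ["C"] * n_c
        return pd.Series(lab, index=idx)

    def test_all_ones_matrix_gives_p_one(self):
        labels = self._labels(2, 2, 2)
        mat = pd.DataFrame(1, index=labels.index, columns=["t0", "t1", "t2"])
        out = tr.permutation_null(mat, labels, "A", n_perm=50, seed=0)
        assert (out["p"] == 1.0).all()

    def test_planted_coenrichment_is_significant(self):
        rng = np.random.default_rng(0)
        labels = self._labels(4, 4, 4)
        n_traits = 24
        mat = pd.DataFrame(0, index=labels.index,
                           columns=[f"t{i}" for i in range(n_traits)])
        # focal tissue A enriched in the first 12 traits; B co-enriched in
        # the same traits (3 per node, disjoint); C spread over all traits
        mat.iloc[0:4, 0:12] = 1
        for i in range(4, 8):
            mat.iloc[i, 3 * (i - 4):3 * (i - 4) + 3] = 1
        for i in range(8, 12):
            cols = rng.choice(n_traits, size=6, replace=False)
            mat.iloc[i, cols] = 1
        out = tr.permutation_null(mat, labels, "A", n_perm=1000, seed=1)
        assert out.set_index("tissue").loc["B", "p"] <= 0.01

    def test_sparse_unswappable_matrix_returns_nan(self):
        labels = self._labels(1, 2, 0)
        mat = pd.DataFrame(0, index=labels.index, columns=["t0", "t1"])
        mat.iloc[1, 0] = 1
        mat.iloc[2, 0] = 1  # ones share a column: no checkerboard
        with pytest.warns(UserWarning, match="too sparse"):
            out = tr.permutation_null(mat, labels, "A", n_perm=10, seed=0)
        assert out["p"].isna().all()

    def test_swaps_preserve_marginals(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            M = (rng.random((12, 15)) < 0.3).astype(np.int8)
            perm = tr._checkerboard_permute(M, 10 * max(1, int(M.sum())), rng)
            assert np.array_equal(perm.sum(axis=0), M.sum(axis=0))
            assert np.array_equal(perm.sum(axis=1), M.sum(axis=1))


class TestTraitNetwork:
    def test_cosine_threshold_rules(self):
        ttm = pd.DataFrame({
            "a": [1.0, 0.0], "b": [1.0, 0.0],        # distance 0 -> edge
            "c": [0.0, 1.0],                          # orthogonal to a -> no edge
            "d": [1 / np.sqrt(2), 1 / np.sqrt(2)],    # 1 - 1/sqrt(2) ~ 0.293
        }, index=["heart", "lung"])
        G = tr.trait_network(ttm, edge_threshold=0.25, layout_seed=0)
        assert G.has_edge("a", "b")
        assert not G.has_edge("a", "c")
        assert not G.has_edge("a", "d")

    def test_edge_set_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        ttm = pd.DataFrame(rng.random((4, 8)),
                           columns=[f"t{i}" for i in range(8)],
                           index=["a", "b", "c", "d"])
        lo = tr.trait_network(ttm, edge_threshold=0.1, layout_seed=0)
        hi = tr.trait_network(ttm, edge_threshold=0.4, layout_seed=0)
        assert set(lo.edges) <= set(hi.edges)

    def test_fewer_than_two_traits_raises(self):
        ttm = pd.DataFrame({"a": [1.0]}, index=["heart"])
        with pytest.raises(ValueError):
            tr.trait_network(ttm)


class TestGeneticOverlapNetwork:
    def _cat(self, rows):
        return pd.DataFrame(rows, columns=["trait", "pubmed_id", "chrom", "pos"])

    def test_identical_snps_give_jaccard_one(self):
        rows = [("a", 1, "c1", 5_000), ("b", 2, "c1", 5_000)]
        out = tr.genetic_overlap_network(self._cat(rows))
        assert out.iloc[0]["jaccard"] == 1.0

    def test_bin_boundary_at_ten_kb(self):
        rows = [("a", 1, "c1", 9_999), ("b", 2, "c1", 10_001)]
        out = tr.genetic_overlap_network(self._cat(rows))
        assert out.empty

    def test_quarter_overlap_passes_default_threshold(self):
        rows = ([("a", 1, "c1", 1 + i * 10_000) for i in range(5)]
                + [("b", 2, "c1", 1 + i * 10_000) for i in range(3, 8)])
        out = tr.genetic_overlap_network(self._cat(rows))
        assert out.iloc[0]["jaccard"] == pytest.approx(2 / 8)


class TestNearestExpressedGene:
    def _world(self):
        enh = pd.DataFrame({"chrom": ["c1"], "start": [10_000], "end": [10_200],
                            "id": ["e0"]})
        tss = pd.DataFrame({"gene": ["near", "far"], "chrom": ["c1", "c1"],
                            "pos": [11_000, 30_000]})
        expr = pd.DataFrame({"s0": [5.0, 5.0], "s1": [5.0, 5.0]},
                            index=["near", "far"])
        return enh, tss, expr

    def test_nearest_expressed_gene_is_chosen(self):
        enh, tss, expr = self._world()
        out = tr.nearest_expressed_gene(enh, tss, expr, ["s0", "s1"])
        assert out.iloc[0]["gene"] == "near"

    def test_low_expression_filtered_before_distance(self):
        enh, tss, expr = self._world()
        expr.loc["near"] = 1.0  # below the 2.0 log2 FPKM floor
        out = tr.nearest_expressed_gene(enh, tss, expr, ["s0", "s1"])
        assert out.iloc[0]["gene"] == "far"

    def test_equidistant_tie_goes_to_lower_coordinate(self):
        enh = pd.DataFrame({"chrom": ["c1"], "start": [10_000], "end": [10_200],
                            "id": ["e0"]})
        tss = pd.DataFrame({"gene": ["hi", "lo"], "chrom": ["c1", "c1"],
                            "pos": [11_100, 9_100]})  # both 1000 from midpoint
        expr = pd.DataFrame({"s0": [5.0, 5.0]}, index=["hi", "lo"])
        out = tr.nearest_expressed_gene(enh, tss, expr, ["s0"])
        assert out.iloc[0]["gene"] == "lo"

    def test_no_expressed_gene_on_chromosome_raises(self):
        enh, tss, expr = self._world()
        expr[:] = 0.0
        with pytest.raises(ValueError, match="no expressed gene"):
            tr.nearest_expressed_gene(enh, tss, expr, ["s0", "s1"])


class TestGenesetOverrepresentation:
    def test_point_mass_probability(self):
        background = [f"g{i}" for i in range(50)]
        table = tr.geneset_overrepresentation(background[:5], {"s": background[:5]},
                                              background)
        assert table.iloc[0]["p_hyper"] == pytest.approx(1 / math.comb(50, 5), rel=1e-12)

    def test_list_equal_set_equal_background_gives_one(self):
        genes = ["a", "b", "c"]
        table = tr.geneset_overrepresentation(genes, {"s": genes}, genes)
        assert table.iloc[0]["p_hyper"] == 1.0

    def test_empty_intersection_gives_one(self):
        table = tr.geneset_overrepresentation(["a"], {"s": ["b"]}, ["a", "b"])
        assert table.iloc[0]["p_hyper"] == 1.0

    def test_list_outside_background_raises(self):
        with pytest.raises(ValueError):
            tr.geneset_overrepresentation(["z"], {"s": ["a"]}, ["a"])


class TestCoassociation:
    def _node(self):
        return pd.DataFrame({"chrom": "c1", "start": np.arange(10) * 20_000,
                             "end": np.arange(10) * 20_000 + 200,
                             "id": [f"e{i}" for i in range(10)]})

    def test_in_overlap_more_significant_gives_small_p(self):
        node = self._node()
        pos = 1 + np.arange(10) * 20_000
        focal = pd.DataFrame({"chrom": "c1", "pos": pos,
                              "neglogp": [20.0] * 5 + [3.0] * 5})
        other = pd.DataFrame({"chrom": "c1", "pos": pos[:5]})
        p = tr.coassociation(focal, other, node)
        assert p < 0.05

    def test_no_signal_gives_unremarkable_p(self):
        node = self._node()
        pos = 1 + np.arange(10) * 20_000
        focal = pd.DataFrame({"chrom": "c1", "pos": pos,
                              "neglogp": [5.0] * 10})
        other = pd.DataFrame({"chrom": "c1", "pos": pos[:5]})
        p = tr.coassociation(focal, other, node)
        assert 0.05 < p <= 1.0

    def test_empty_overlap_side_returns_nan(self):
        node = self._node()
        focal = pd.DataFrame({"chrom": "c1", "pos": 1 + np.arange(10) * 20_000,
                              "neglogp": np.arange(10.0)})
        other = pd.DataFrame({"chrom": "c9", "pos": [1]})
        assert math.isnan(tr.coassociation(focal, other, node))
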