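"""Catalog pruning, overlap rule, enrichment tests, biosample tree."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from enhancerkit import gwas as gw
from enhancerkit._stats import hypergeom_tail


def catalog_from(rows):
    return pd.DataFrame(rows, columns=["trait", "pubmed_id", "chrom", "pos",
                                       "pvalue", "sample_size"])


class TestPruneCatalog:
    def test_greedy_five_kb_rule(self):
        rows = [("t", 1, "c1", 100_000, 1e-20, 50_000),
                ("t", 1, "c1", 103_000, 1e-12, 50_000),
                ("t", 1, "c1", 110_000, 1e-9, 50_000)]
        pruned = gw.prune_catalog(catalog_from(rows), min_snps=1)
        assert sorted(pruned["pos"]) == [100_000, 110_000]

    def test_hla_interval_removed_regardless_of_pvalue(self):
        rows = [("t", 1, "chr6", 30_000_000, 1e-300, 50_000)] + [
            ("t", 1, "c1", 10_000 + 20_000 * i, 1e-10, 50_000) for i in range(12)]
        pruned = gw.prune_catalog(catalog_from(rows))
        assert (pruned["chrom"] != "chr6").all()

    def test_study_with_too_few_kept_snps_dropped(self):
        rows = [("t", 1, "c1", 10_000 + 20_000 * i, 1e-10, 50_000) for i in range(9)]
        assert gw.prune_catalog(catalog_from(rows)).empty

    def test_underpowered_study_dropped(self):
        rows = [("t", 1, "c1", 10_000 + 20_000 * i, 1e-10, 5_000) for i in range(12)]
        assert gw.prune_catalog(catalog_from(rows)).empty

    def test_random_catalogs_satisfy_contract(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rows = []
            for t in range(3):
                n = rng.integers(5, 40)
                chroms = rng.choice(["c1", "c2", "chr6"], size=n)
                pos = rng.integers(1, 40_000_000, size=n)
                for c, p in zip(chroms, pos):
                    rows.append((f"t{t}", t, c, int(p), float(rng.random()),
                                 int(rng.integers(1_000, 100_000))))
            pruned = gw.prune_catalog(catalog_from(rows))
            for (_, _), study in pruned.groupby(["trait", "pubmed_id"]):
                assert len(study) >= 10
                assert study["sample_size"].max() >= 10_000
                for c, sub in study.groupby("chrom"):
                    p = np.sort(sub["pos"].to_numpy())
                    assert (np.diff(p) > 5_000).all()
            hla = pruned[(pruned["chrom"] == "chr6")
                         & pruned["pos"].between(29_691_116, 33_054_976)]
            assert hla.empty

    def test_malformed_positions_raise(self):
        rows = [("t", 1, "c1", 0, 1e-10, 50_000)]
        with pytest.raises(ValueError):
            gw.prune_catalog(catalog_from(rows))


class TestSnpEnhancerOverlap:
    enh = pd.DataFrame({"chrom": ["c1"], "start": [1000], "end": [1200], "id": ["e"]})

    @pytest.mark.parametrize("chrom,pos,hit", [
        ("c1", 3601, True),    # midpoint 1100 -> 1-based 1101; distance 2500
        ("c1", 3602, False),
        ("c2", 3601, False),
    ])
    def test_midpoint_radius_boundary(self, chrom, pos, hit):
        snps = pd.DataFrame({"chrom": [chrom], "pos": [pos]})
        hits = gw.snp_enhancer_overlap(snps, self.enh)
        assert (len(hits) == 1) is hit


class TestFlatEnrichment:
    def _world(self):
        # 20 catalog SNPs on a line, enhancers covering the first few
        enh = pd.DataFrame({"chrom": "c1", "start": np.arange(5) * 20_000,
                            "end": np.arange(5) * 20_000 + 200,
                            "id": [f"e{i}" for i in range(5)]})
        rows = []
        for i in range(20):
            trait = "t0" if i < 10 else "t1"
            rows.append((trait, 1, "c1", 1 + i * 20_000, 1e-10, 50_000))
        return catalog_from(rows), enh

    def test_counts_and_exact_tail(self):
        cat, enh = self._world()
        table = gw.flat_enrichment(cat, {"s": set(enh["id"])}, enh)
        row = table[table["trait"] == "t0|1"].iloc[0]
        assert (row["k"], row["K"], row["n"], row["N"]) == (5, 5, 10, 20)
        exact = sum(math.comb(5, j) * math.comb(15, 10 - j) for j in range(5, 6))
        assert row["p_hyper"] == pytest.approx(exact / math.comb(20, 10), rel=1e-12)

    def test_everything_in_set_gives_p_one(self):
        assert hypergeom_tail(10, 10, 10, 10) == 1.0

    def test_zero_overlap_gives_p_one(self):
        assert hypergeom_tail(0, 20, 5, 10) == 1.0

    def test_reference_table_value(self):
        exact = (math.comb(5, 4) * math.comb(15, 6) + math.comb(5, 5) * math.comb(15, 5)
                 ) / math.comb(20, 10)
        assert hypergeom_tail(4, 20, 5, 10) == pytest.approx(exact, rel=1e-12)
        assert hypergeom_tail(4, 20, 5, 10) == pytest.approx(0.15167, abs=5e-5)

    def test_bh_significant_set_is_pvalue_prefix(self):
        cat, enh = self._world()
        sets = {f"s{i}": {f"e{j}" for j in range(i + 1)} for i in range(5)}
        table = gw.flat_enrichment(cat, sets, enh, alpha=0.3)
        sig = table[table["significant"]]["p_hyper"]
        if not sig.empty:
            assert sig.max() <= table[~table["significant"]]["p_hyper"].min()


class TestEmpiricalFdr:
    def test_set_capturing_every_snp_yields_nan_with_warning(self):
        cat, _ = TestFlatEnrichment()._world()
        enh = pd.DataFrame({"chrom": "c1", "start": np.arange(20) * 20_000,
                            "end": np.arange(20) * 20_000 + 200,
                            "id": [f"e{i}" for i in range(20)]})
        with pytest.warns(UserWarning, match="FDR undefined"):
            fdr, real, _ = gw.empirical_fdr(cat, {"all": set(enh["id"])}, enh,
                                            n_shuffles=5, seed=0)
        assert math.isnan(fdr) and real == 0

    def test_fixed_seed_reproduces_shuffles(self):
        cat, enh = TestFlatEnrichment()._world()
        sets = {"s": {"e0", "e1"}}
        a = gw.empirical_fdr(cat, sets, enh, n_shuffles=10, seed=4,
                             significance="nominal")
        b = gw.empirical_fdr(cat, sets, enh, n_shuffles=10, seed=4,
                             significance="nominal")
        assert np.array_equal(a[2], b[2])


def random_activity(rng, n_samples, n_elements=30):
    frame = pd.DataFrame(
        (rng.random((n_elements, n_samples)) < 0.5).astype(int),
        index=[f"e{i}" for i in range(n_elements)],
        columns=[f"s{i}" for i in range(n_samples)])
    return frame


class TestBuildTree:
    def test_identical_samples_merge_first_at_zero(self):
        frame = pd.DataFrame({"s0": [1, 0, 1], "s1": [1, 0, 1], "s2": [0, 1, 0]},
                             index=["e0", "e1", "e2"])
        tree = gw.build_tree(frame)
        first_internal = tree.nodes[3]
        assert set(first_internal.leaves) == {"s0", "s1"}
        assert first_internal.height == 0.0

    def test_root_consensus_is_global_intersection(self):
        rng = np.random.default_rng(1)
        frame = random_activity(rng, 6)
        tree = gw.build_tree(frame)
        expected = frame.all(axis=1).to_numpy()
        assert np.array_equal(tree.nodes[tree.root].consensus, expected)

    def test_merge_heights_match_scipy_complete_linkage(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            frame = random_activity(rng, rng.integers(3, 9))
            tree = gw.build_tree(frame)
            D = pdist(frame.to_numpy().T.astype(bool), metric="jaccard")
            Z = linkage(D, method="complete")
            mine = sorted(n.height for n in tree.nodes.values() if n.children)
            assert np.allclose(mine, np.sort(Z[:, 2]))

    def test_consensus_superset_chain_and_disjoint_tested_sets(self):
        rng = np.random.default_rng(3)
        frame = random_activity(rng, 8)
        tree = gw.build_tree(frame)
        for i, node in tree.nodes.items():
            if node.parent is not None:
                parent = tree.nodes[node.parent]
                assert not (parent.consensus & ~node.consensus).any()
                # ancestor tested sets are disjoint from this node's
                anc = parent
                while anc is not None:
                    assert not (node.tested & anc.tested).any()
                    anc = tree.nodes[anc.parent] if anc.parent is not None else None

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            gw.build_tree(pd.DataFrame({"s0": [1, 0]}))


class TestTreeEnrichment:
    def test_empty_tested_set_skipped(self):
        frame = pd.DataFrame({"s0": [1, 1], "s1": [1, 1], "s2": [1, 0]},
                             index=["e0", "e1"])
        tree = gw.build_tree(frame)
        # s0 and s1 identical: the child node's consensus equals its leaf sets;
        # at least one node's tested set is empty somewhere in this tree
        enh = pd.DataFrame({"chrom": "c1", "start": [0, 20_000],
                            "end": [200, 20_200], "id": ["e0", "e1"]})
        rows = [("t", 1, "c1", 1 + i * 20_000, 1e-10, 50_000) for i in range(12)]
        table = gw.tree_enrichment(catalog_from(rows), tree, enh)
        leaf_ids = {i for i, n in tree.nodes.items() if n.children is None}
        skipped = set(table[table["skipped"] == True]["node"])  # noqa: E712
        empty = {i for i, n in tree.nodes.items() if n.tested.sum() == 0}
        assert empty and empty == skipped

    def test_leaf_tested_set_is_leaf_minus_parent(self):
        rng = np.random.default_rng(4)
        frame = random_activity(rng, 5)
        tree = gw.build_tree(frame)
        for i in tree.leaves():
            node = tree.nodes[i]
            parent = tree.nodes[node.parent]
            expected = node.consensus & ~parent.consensus
            assert np.array_equal(node.tested, expected)

    def test_full_consensus_variant(self):
        rng = np.random.default_rng(5)
        frame = random_activity(rng, 4)
        tree = gw.build_tree(frame)
        enh = pd.DataFrame({"chrom": "c1", "start": np.arange(30) * 20_000,
                            "end": np.arange(30) * 20_000 + 200,
                            "id": [f"e{i}" for i in range(30)]})
        rows = [("t", 1, "c1", 1 + i * 20_000, 1e-10, 50_000) for i in range(15)]
        table = gw.tree_enrichment(catalog_from(rows), tree, enh, tested="consensus")
        done = table[table["skipped"] == False]  # noqa: E712
        for _, row in done.iterrows():
            assert row["tested_size"] == row["consensus_size"]


class TestRarefaction:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["set", "trait", "p_hyper", "significant"])
        return df

    def test_single_covering_set_gives_one_step(self):
        rows = [("s1", t, 1e-5, True) for t in ("t1", "t2", "t3")]
        rows += [("s2", t, 0.5, False) for t in ("t1", "t2", "t3")]
        curve = gw.rarefaction_curve(self._table(rows))
        assert curve == [("s1", ["t1", "t2", "t3"])]

    def test_disjoint_coverage_ordered_by_size(self):
        rows = [("s1", "t1", 1e-5, True), ("s1", "t2", 1e-5, True),
                ("s1", "t3", 0.9, False),
                ("s2", "t3", 1e-5, True), ("s2", "t1", 0.9, False),
                ("s2", "t2", 0.9, False)]
        curve = gw.rarefaction_curve(self._table(rows))
        assert [c[0] for c in curve] == ["s1", "s2"]

    def test_first_step_matches_bruteforce_best(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            rows = []
            for s in range(6):
                for t in range(8):
                    p = float(rng.random())
                    rows.append((f"s{s}", f"t{t}", p, p < 0.05))
            table = self._table(rows)
            curve = gw.rarefaction_curve(table)
            # brute force: coverage counts of the first pick
            sig = table[table["significant"]]
            cover = {s: set(g["trait"]) for s, g in sig.groupby("set")}
            no_sig = set(table["trait"]) - set(sig["trait"])
            for t in no_sig:
                sub = table[table["trait"] == t].sort_values(["p_hyper", "set"])
                cover.setdefault(sub.iloc[0]["set"], set()).add(t)
            best = max(len(v) for v in cover.values())
            assert len(curve[0][1]) == best
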