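"""GWAS catalog pruning and flat / tree-based enrichment analysis.

Catalog conventions: associations carry 1-based SNP positions; a study
is a (trait, pubmed_id) pair.  Enhancers are BED intervals (0-based
half-open); a SNP hits an enhancer when it lies within 2.5 kb of the
enhancer midpoint (midpoint converted to 1-based, boundary inclusive).

Enrichment of a study in an annotation set uses the upper-tail
hypergeometric probability on unique-SNP counts: ``k`` study SNPs in
the set, ``K`` catalog SNPs in the set, ``n`` study SNPs, ``N`` catalog
SNPs; a SNP shared between studies counts once for K/N and per study
for k/n.  BH correction treats all (set, study) pairs of a run as one
family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust, hypergeom_tail, hypergeom_tail_vec

HLA_LOCUS = ("chr6", 29_691_116, 33_054_976)
STUDY_COLS = ["trait", "pubmed_id"]


def study_key(catalog: pd.DataFrame) -> pd.Series:
    return catalog["trait"].astype(str) + "|" + catalog["pubmed_id"].astype(str)


def prune_catalog(catalog: pd.DataFrame, window_bp: int = 5_000,
                  hla: tuple = HLA_LOCUS, min_sample_size: int = 10_000,
                  min_snps: int = 10) -> pd.DataFrame:
    """Greedy per-study pruning plus HLA and power filters.

    Within each study, associations are ranked by p-value and kept
    iff farther than ``window_bp`` from every previously kept SNP on
    the same chromosome.  All associations inside the HLA interval are
    removed first; studies with sample size below ``min_sample_size`` or
    fewer than ``min_snps`` kept SNPs are dropped entirely.
    """
    cat = catalog.copy()
    pos = pd.to_numeric(cat["pos"], errors="raise")
    if (pos < 1).any() or not np.allclose(pos, np.round(pos)):
        raise ValueError("positions must be 1-based positive integers")
    cat["pos"] = pos.astype(np.int64)
    in_hla = (cat["chrom"] == hla[0]) & (cat["pos"] >= hla[1]) & (cat["pos"] <= hla[2])
    cat = cat[~in_hla]
    kept_parts = []
    for _, study in cat.groupby(STUDY_COLS, sort=True):
        study = study.sort_values(["pvalue", "chrom", "pos"], kind="stable")
        kept_pos: dict[str, list[int]] = {}
        keep_idx = []
        for idx, chrom, p in zip(study.index, study["chrom"], study["pos"]):
            prior = kept_pos.setdefault(chrom, [])
            if all(abs(int(p) - q) > window_bp for q in prior):
                prior.append(int(p))
                keep_idx.append(idx)
        kept = study.loc[keep_idx]
        if len(kept) >= min_snps and kept["sample_size"].max() >= min_sample_size:
            kept_parts.append(kept)
    if not kept_parts:
        return cat.iloc[0:0]
    out = pd.concat(kept_parts)
    return out.sort_values(STUDY_COLS + ["chrom", "pos"], kind="stable").reset_index(drop=True)


def snp_enhancer_overlap(snps: pd.DataFrame, enhancers: pd.DataFrame,
                         radius_bp: int = 2_500) -> pd.DataFrame:
    """All (SNP, enhancer) pairs with ``|pos - midpoint_1based| <= radius``."""
    mid1 = (enhancers["start"].to_numpy() + enhancers["end"].to_numpy()) // 2 + 1
    rows = []
    for chrom, sub_e in enhancers.assign(mid1=mid1).groupby("chrom", sort=True):
        sub_s = snps[snps["chrom"] == chrom]
        if sub_s.empty:
            continue
        order = np.argsort(sub_e["mid1"].to_numpy(), kind="stable")
        emid = sub_e["mid1"].to_numpy()[order]
        eid = sub_e["id"].to_numpy()[order] if "id" in sub_e else sub_e["name"].to_numpy()[order]
        p = sub_s["pos"].to_numpy()
        lo = np.searchsorted(emid, p - radius_bp, side="left")
        hi = np.searchsorted(emid, p + radius_bp, side="right")
        for si, l, h in zip(sub_s.index, lo, hi):
            for j in range(l, h):
                rows.append((si, chrom, int(snps.at[si, "pos"]), eid[j]))
    return pd.DataFrame(rows, columns=["snp_index", "chrom", "pos", "enhancer"])


def _snp_set_hits(catalog: pd.DataFrame, enhancers: pd.DataFrame,
                  annotation_sets: dict[str, object], radius_bp: int):
    """Unique SNPs, their per-set hit masks and per-study membership."""
    snps = catalog[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    snps["snp_id"] = snps["chrom"].astype(str) + ":" + snps["pos"].astype(str)
    hits = snp_enhancer_overlap(snps, enhancers, radius_bp)
    enh_by_snp = hits.groupby("snp_index")["enhancer"].agg(set)
    set_masks = {}
    for set_id, members in annotation_sets.items():
        members = set(members)
        mask = np.zeros(len(snps), dtype=bool)
        for si, enh_ids in enh_by_snp.items():
            if enh_ids & members:
                mask[si] = True
        set_masks[set_id] = mask
    snp_index = pd.Series(np.arange(len(snps)), index=snps["snp_id"])
    cat_ids = catalog["chrom"].astype(str) + ":" + catalog["pos"].astype(str)
    return snps, set_masks, snp_index, cat_ids


def _pair_table(set_masks: dict, snp_index: pd.Series, cat_ids: pd.Series,
                skey: np.ndarray, alpha: float) -> pd.DataFrame:
    N = len(snp_index)
    study_uniq = {key: snp_index[sub.unique()].to_numpy()
                  for key, sub in cat_ids.groupby(skey)}
    rows = []
    for set_id, mask in set_masks.items():
        K = int(mask.sum())
        for key, uniq in study_uniq.items():
            rows.append((set_id, key, int(mask[uniq].sum()), K, len(uniq), N))
    table = pd.DataFrame(rows, columns=["set", "trait", "k", "K", "n", "N"])
    table["p_hyper"] = hypergeom_tail_vec(table["k"], table["N"], table["K"], table["n"])
    table["p_bh"] = bh_adjust(table["p_hyper"])
    table["significant"] = table["p_bh"] < alpha
    return table


def flat_enrichment(catalog: pd.DataFrame, annotation_sets: dict[str, object],
                    enhancers: pd.DataFrame, radius_bp: int = 2_500,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of every study in every annotation set.

    ``annotation_sets`` maps a set id to a collection of enhancer ids
    (matching the ``id``/``name`` column of ``enhancers``).  Returns one
    row per (set, study) with the 2x2 counts, the upper-tail p-value,
    its BH adjustment over all pairs jointly, and the significance flag
    at ``alpha``.
    """
    if catalog.empty:
        raise ValueError("empty catalog")
    snps, set_masks, snp_index, cat_ids = _snp_set_hits(
        catalog, enhancers, annotation_sets, radius_bp)
    return _pair_table(set_masks, snp_index, cat_ids, study_key(catalog).to_numpy(), alpha)


def empirical_fdr(catalog: pd.DataFrame, annotation_sets: dict[str, object],
                  enhancers: pd.DataFrame, n_shuffles: int = 100, seed: int = 0,
                  radius_bp: int = 2_500, alpha: float = 0.05,
                  significance: str = "bh") -> tuple[float, int, np.ndarray]:
    """Empirical FDR by shuffling study labels across associations.

    The (trait, pubmed_id) label pair is permuted globally over
    association rows (positions fixed), breaking genotype-phenotype
    structure while preserving study sizes.  The estimate is the mean
    number of significant (set, study) pairs over shuffles divided by
    the real count; ``significance`` is either BH at ``alpha`` ('bh') or
    the raw p-value threshold ('nominal').  Returns (fdr, real
    significant count, per-shuffle counts); a real count of zero yields
    NaN with a warning.
    """
    if catalog[STUDY_COLS].drop_duplicates().shape[0] < 2:
        raise ValueError("need at least 2 studies to shuffle")

    if significance not in ("bh", "nominal"):
        raise ValueError(f"unknown significance rule: {significance}")
    snps, set_masks, snp_index, cat_ids = _snp_set_hits(
        catalog, enhancers, annotation_sets, radius_bp)

    def n_significant(skey: np.ndarray) -> int:
        table = _pair_table(set_masks, snp_index, cat_ids, skey, alpha)
        if significance == "bh":
            return int(table["significant"].sum())
        return int((table["p_hyper"] < alpha).sum())

    labels = study_key(catalog).to_numpy()
    real = n_significant(labels)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_shuffles, dtype=int)
    for i in range(n_shuffles):
        counts[i] = n_significant(labels[rng.permutation(len(labels))])
    if real == 0:
        warnings.warn("no significant combinations in the real catalog; FDR undefined")
        return float("nan"), real, counts
    return float(counts.mean() / real), real, counts


# --------------------------------------------------------------------------
# Biosample tree


@dataclass
class TreeNode:
    id: int
    children: tuple[int, int] | None   # None for leaves
    parent: int | None
    height: float
    leaves: tuple[str, ...]
    consensus: np.ndarray              # bool over enhancer rows
    tested: np.ndarray | None = None   # consensus minus parent consensus


@dataclass
class BiosampleTree:
    """Complete-linkage merge tree with per-node consensus enhancer sets."""

    samples: list[str]
    element_ids: list[str]
    nodes: dict[int, TreeNode] = field(default_factory=dict)
    root: int = -1

    def node_ids(self) -> list[int]:
        return sorted(self.nodes)

    def leaves(self) -> list[int]:
        return [i for i, n in self.nodes.items() if n.children is None]

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            n = self.nodes[i]
            if n.children is None:
                return f"{n.leaves[0]}:{n.height:.6f}"
            a, b = n.children
            return f"({rec(a)},{rec(b)})node{i}:{n.height:.6f}"
        return rec(self.root) + ";"


def build_tree(activity) -> BiosampleTree:
    """Complete-linkage tree over biosamples under 1 - Jaccard of enhancer sets.

    Naive O(n^3) agglomeration with a documented deterministic
    tie-break: among minimal-distance cluster pairs, the pair whose
    member clusters contain the smallest original sample indices wins.
    Consensus sets are intersections computed bottom-up, so every node's
    consensus is a superset of its parent's; the tested set is the
    consensus minus the parent consensus (the root tests its full
    consensus).
    """
    frame = activity.to_frame() if hasattr(activity, "to_frame") else pd.DataFrame(activity)
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 biosamples")
    if frame.size == 0:
        raise ValueError("empty activity matrix")
    samples = list(frame.columns)
    X = frame.to_numpy().astype(bool).T  # samples x enhancers
    inter = X.astype(np.float64) @ X.T.astype(np.float64)
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        D = 1.0 - inter / union
    D[union == 0] = 0.0

    tree = BiosampleTree(samples=samples, element_ids=list(frame.index))
    active: dict[int, dict] = {}
    for i, s in enumerate(samples):
        tree.nodes[i] = TreeNode(i, None, None, 0.0, (s,), X[i].copy())
        active[i] = {"members": [i], "rank": i}
    dist: dict[tuple[int, int], float] = {}
    ids = sorted(active)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            dist[(ids[a], ids[b])] = float(D[ids[a], ids[b]])
    next_id = len(samples)
    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], active[kv[0][0]]["rank"], active[kv[0][1]]["rank"]),
        )
        (a, b), h = best
        na, nb = tree.nodes[a], tree.nodes[b]
        consensus = na.consensus & nb.consensus
        node = TreeNode(next_id, (a, b), None, h, na.leaves + nb.leaves, consensus)
        tree.nodes[next_id] = node
        na.parent = nb.parent = next_id
        merged = {"members": active[a]["members"] + active[b]["members"],
                  "rank": min(active[a]["rank"], active[b]["rank"])}
        del active[a], active[b]
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        for other in active:
            pairs = [(min(i, j), max(i, j)) for i in merged["members"]
                     for j in active[other]["members"]]
            d = max(float(D[i, j]) for i, j in pairs)
            dist[(min(other, next_id), max(other, next_id))] = d
        active[next_id] = merged
        next_id += 1
    tree.root = next_id - 1
    for i, n in tree.nodes.items():
        if n.parent is None:
            n.tested = n.consensus.copy()
        else:
            n.tested = n.consensus & ~tree.nodes[n.parent].consensus
    return tree


def tree_enrichment(catalog: pd.DataFrame, tree: BiosampleTree,
                    enhancers: pd.DataFrame, radius_bp: int = 2_500,
                    alpha: float = 0.05, tested: str = "node_minus_parent"
                    ) -> pd.DataFrame:
    """Hypergeometric enrichment of every study at every tree node.

    ``tested='node_minus_parent'`` (default) tests each node's
    differential set — consensus minus parent consensus; ``'consensus'``
    tests the full consensus set.  Nodes with an empty tested set are
    skipped and recorded with ``skipped=True``.  BH is applied over all
    performed (node, study) tests jointly.
    """
    eid = enhancers["id"] if "id" in enhancers else enhancers["name"]
    id_arr = eid.to_numpy()
    sets: dict[str, object] = {}
    meta = []
    for i in tree.node_ids():
        node = tree.nodes[i]
        mask = node.tested if tested == "node_minus_parent" else node.consensus
        if tested not in ("node_minus_parent", "consensus"):
            raise ValueError(f"unknown tested-set rule: {tested}")
        meta.append((i, int(mask.sum()), int(node.consensus.sum()), len(node.leaves)))
        if mask.sum() == 0:
            continue
        sets[str(i)] = set(np.array(tree.element_ids)[mask])
    meta_df = pd.DataFrame(meta, columns=["node", "tested_size", "consensus_size", "n_leaves"])
    if not sets:
        out = meta_df.assign(skipped=True)
        return out
    table = flat_enrichment(catalog, sets, enhancers, radius_bp, alpha)
    table = table.rename(columns={"set": "node"})
    table["node"] = table["node"].astype(int)
    table = table.merge(meta_df, on="node", how="left")
    skipped = meta_df[~meta_df["node"].isin(table["node"])].assign(skipped=True)
    table["skipped"] = False
    return pd.concat([table, skipped], ignore_index=True)


def rarefaction_curve(table: pd.DataFrame) -> list[tuple[str, list[str]]]:
    """Greedy cover of traits by annotation sets.

    At each step the set covering the most uncovered traits is added
    (a set covers a trait when significantly enriched for it, or — for
    traits with no significant set anywhere — when it holds that trait's
    maximal enrichment).  Ties break on the set id.  Returns the chosen
    sets with the traits each newly covers.
    """
    if table.empty:
        raise ValueError("empty enrichment table")
    cover: dict[str, set] = {s: set() for s in table["set"].unique()}
    sig_traits = set(table.loc[table["significant"], "trait"])
    for _, row in table[table["significant"]].iterrows():
        cover[row["set"]].add(row["trait"])
    for trait, sub in table.groupby("trait"):
        if trait in sig_traits:
            continue
        best = sub.sort_values(["p_hyper", "set"], kind="stable").iloc[0]
        cover[best["set"]].add(trait)
    uncovered = set(table["trait"].unique())
    curve = []
    while uncovered:
        best_set = min(cover, key=lambda s: (-len(cover[s] & uncovered), str(s)))
        newly = sorted(cover[best_set] & uncovered)
        if not newly:
            break
        curve.append((best_set, newly))
        uncovered -= set(newly)
    return curve
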