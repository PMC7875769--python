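"""Tissue-level aggregation of tree enrichments and cross-trait analysis.

Internal tree nodes are labeled with a tissue group when strictly more
than half of their subtree leaves come from that group ("multiple"
otherwise).  Summing -log10 p over each tissue's significant nodes
gives a tissue x trait matrix, which feeds trait classification
(unifactorial / multifactorial / polyfactorial), tissue Jaccard
similarity with a fixed-marginal permutation null, and the cosine
cross-trait network; a genetic-overlap network from shared 10-kb SNP
bins complements the epigenetic one.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cosine as cosine_distance

from ._stats import bh_adjust, hypergeom_tail
from .gwas import BiosampleTree, snp_enhancer_overlap, STUDY_COLS


def assign_node_tissues(tree: BiosampleTree, metadata: pd.DataFrame) -> pd.Series:
    """Tissue label per tree node: strict-majority tissue of leaves else 'multiple'."""
    md = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    missing = set(tree.samples) - set(md.index)
    if missing:
        raise ValueError(f"leaves without metadata: {sorted(missing)}")
    groups = md["tissue_group"]
    labels = {}
    for i in tree.node_ids():
        leaves = tree.nodes[i].leaves
        counts = pd.Series([groups[s] for s in leaves]).value_counts()
        top, top_n = counts.index[0], counts.iloc[0]
        labels[i] = top if top_n * 2 > len(leaves) else "multiple"
    return pd.Series(labels, name="tissue")


def tissue_trait_matrix(enrichments: pd.DataFrame, node_labels: pd.Series,
                        significant_only: bool = True,
                        normalize: bool = False) -> pd.DataFrame:
    """Tissue x trait matrix of summed -log10 p over each tissue's nodes.

    Restricted to BH-significant (node, trait) entries by default.
    ``normalize=True`` scales each trait column to sum to 1 (zero
    columns stay zero).
    """
    table = enrichments.dropna(subset=["p_hyper"])
    unknown = set(table["node"].astype(int)) - set(node_labels.index)
    if unknown:
        raise ValueError(f"enrichment nodes absent from the label table: {sorted(unknown)}")
    if significant_only:
        table = table[table["significant"]]
    tissues = sorted(set(node_labels)) + (["multiple"] if "multiple" not in set(node_labels) else [])
    traits = sorted(enrichments["trait"].dropna().unique())
    mat = pd.DataFrame(0.0, index=tissues, columns=traits)
    for _, row in table.iterrows():
        t = node_labels[int(row["node"])]
        mat.loc[t, row["trait"]] += -np.log10(max(row["p_hyper"], 1e-300))
    if normalize:
        sums = mat.sum(axis=0)
        nz = sums > 0
        mat.loc[:, nz] = mat.loc[:, nz] / sums[nz]
    return mat


def classify_traits(binary_matrix: pd.DataFrame, poly_threshold: int = 10) -> pd.DataFrame:
    """Classify traits by the number of enriched tissue groups.

    Exactly one enriched group -> unifactorial; two or more ->
    multifactorial; at or above ``poly_threshold`` additionally flagged
    polyfactorial.  Traits enriched nowhere are excluded with a warning.
    """
    counts = binary_matrix.astype(bool).sum(axis=0)
    empty = counts[counts == 0].index
    if len(empty):
        warnings.warn(f"{len(empty)} trait(s) with no enriched tissue excluded")
    counts = counts[counts > 0]
    cls = np.where(counts == 1, "unifactorial", "multifactorial")
    return pd.DataFrame({
        "trait": counts.index,
        "n_tissues": counts.to_numpy(),
        "class": cls,
        "polyfactorial": counts.to_numpy() >= poly_threshold,
    }).reset_index(drop=True)


def tissue_similarity(binary_matrix: pd.DataFrame) -> pd.DataFrame:
    """Jaccard similarity between tissues over their enriched trait sets."""
    B = binary_matrix.astype(bool).to_numpy()
    inter = B.astype(float) @ B.T.astype(float)
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = inter / union
    J[union == 0] = 0.0
    return pd.DataFrame(J, index=binary_matrix.index, columns=binary_matrix.index)


def _checkerboard_permute(sub: np.ndarray, n_swaps: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving rewiring by random checkerboard swaps.

    Attempts ``n_swaps`` swaps: two 1-entries in distinct rows and
    columns trade corners when the opposite corners are 0.  Row and
    column sums are invariant by construction.
    """
    M = sub.copy()
    ones = np.argwhere(M == 1)
    if len(ones) < 2:
        return M
    for _ in range(n_swaps):
        i, j = rng.integers(0, len(ones), size=2)
        (r1, c1), (r2, c2) = ones[i], ones[j]
        if r1 == r2 or c1 == c2:
            continue
        if M[r1, c2] == 0 and M[r2, c1] == 0:
            M[r1, c1] = M[r2, c2] = 0
            M[r1, c2] = M[r2, c1] = 1
            ones[i] = (r1, c2)
            ones[j] = (r2, c1)
    return M


def _has_checkerboard(M: np.ndarray) -> bool:
    ones = np.argwhere(M == 1)
    for a in range(len(ones)):
        r1, c1 = ones[a]
        for b in range(a + 1, len(ones)):
            r2, c2 = ones[b]
            if r1 != r2 and c1 != c2 and M[r1, c2] == 0 and M[r2, c1] == 0:
                return True
    return False


def permutation_null(node_trait: pd.DataFrame, node_labels: pd.Series,
                     focal_tissue: str, n_perm: int = 10_000, seed: int = 0,
                     swaps_per_one: int = 10) -> pd.DataFrame:
    """Fixed-marginal permutation test of tissue co-enrichment.

    The rows of the binary node x trait matrix belonging to the focal
    tissue's nodes stay fixed; the remaining block is rewired by
    ``swaps_per_one x (number of ones)`` checkerboard swaps per
    permutation (marginals asserted invariant each iteration).  Each
    permuted matrix is collapsed to tissue x trait (a tissue is enriched
    in a trait when any of its nodes is), and for every other tissue the
    trait-overlap with the focal tissue is compared to its permuted
    distribution: ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    Also reports the mean cosine distance between permuted and original
    matrices.  If the permutable block admits no checkerboard swap and
    is not constant, p-values are returned as NaN with a warning.
    """
    B = node_trait.astype(bool).astype(np.int8).to_numpy()
    labels = node_labels.loc[node_trait.index]
    focal_rows = (labels == focal_tissue).to_numpy()
    if not focal_rows.any():
        raise ValueError(f"no nodes labeled {focal_tissue}")
    sub = B[~focal_rows]
    tissues = sorted(set(labels) - {focal_tissue})

    def collapse(M: np.ndarray) -> dict[str, np.ndarray]:
        full = B.copy()
        full[~focal_rows] = M
        return {t: full[(labels == t).to_numpy()].any(axis=0) for t in tissues}

    focal_vec = B[focal_rows].any(axis=0)
    observed = {t: int((focal_vec & v).sum()) for t, v in collapse(sub).items()}

    degenerate = sub.size > 0 and not _has_checkerboard(sub)
    constant = sub.size == 0 or sub.min() == sub.max()
    if degenerate and not constant:
        warnings.warn("matrix too sparse to swap; permutation p-values undefined")
        return pd.DataFrame({"tissue": tissues,
                             "observed_overlap": [observed[t] for t in tissues],
                             "p": np.nan, "mean_cosine_distance": np.nan})

    rng = np.random.default_rng(seed)
    n_swaps = swaps_per_one * max(1, int(sub.sum()))
    row_sums, col_sums = sub.sum(axis=1), sub.sum(axis=0)
    ge = {t: 0 for t in tissues}
    cosines = np.zeros(n_perm)
    flat0 = B.flatten().astype(float)
    for it in range(n_perm):
        perm = _checkerboard_permute(sub, n_swaps, rng)
        assert np.array_equal(perm.sum(axis=1), row_sums)
        assert np.array_equal(perm.sum(axis=0), col_sums)
        coll = collapse(perm)
        for t in tissues:
            if int((focal_vec & coll[t]).sum()) >= observed[t]:
                ge[t] += 1
        full = B.copy()
        full[~focal_rows] = perm
        flat = full.flatten().astype(float)
        cosines[it] = 0.0 if (flat0.sum() == 0 or flat.sum() == 0) else cosine_distance(flat0, flat)
    return pd.DataFrame({
        "tissue": tissues,
        "observed_overlap": [observed[t] for t in tissues],
        "p": [(1 + ge[t]) / (1 + n_perm) for t in tissues],
        "mean_cosine_distance": float(cosines.mean()),
    })


def trait_network(ttm: pd.DataFrame, edge_threshold: float = 0.25,
                  min_neglogp: float = 0.0, layout_seed: int = 0,
                  trait_max_neglogp: pd.Series | None = None) -> nx.Graph:
    """Cross-trait network from cosine distances of tissue profiles.

    ``ttm`` is the column-normalized tissue x trait matrix.  Traits with
    maximal -log10 p below ``min_neglogp`` (when provided) are dropped;
    edges connect traits at cosine distance <= ``edge_threshold``, carry
    the dominant tissue (argmax of the elementwise profile product), and
    a deterministic spring layout is stored as node positions.
    """
    cols = [c for c in ttm.columns if ttm[c].sum() > 0]
    if trait_max_neglogp is not None:
        cols = [c for c in cols if trait_max_neglogp.get(c, 0.0) >= min_neglogp]
    if len(cols) < 2:
        raise ValueError("need at least 2 traits with signal")
    M = ttm[cols].to_numpy(dtype=float)
    M = M / M.sum(axis=0, keepdims=True)
    G = nx.Graph()
    for c in cols:
        G.add_node(c, tissue=ttm.index[int(np.argmax(ttm[c].to_numpy()))])
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            d = cosine_distance(M[:, i], M[:, j])
            if d <= edge_threshold:
                prod = M[:, i] * M[:, j]
                G.add_edge(cols[i], cols[j], cosine_distance=float(d),
                           tissue=ttm.index[int(np.argmax(prod))])
    pos = nx.spring_layout(G, seed=layout_seed)
    nx.set_node_attributes(G, {n: tuple(p) for n, p in pos.items()}, "pos")
    return G


def genetic_overlap_network(catalog: pd.DataFrame, bin_bp: int = 10_000,
                            min_jaccard: float = 0.01) -> pd.DataFrame:
    """Trait-trait edges from shared 10-kb SNP bins of the pruned catalog.

    Bins start at the beginning of each chromosome (1-based position p
    maps to bin ``(p - 1) // bin_bp``); an edge is reported when the
    Jaccard similarity of the two traits' occupied bin sets reaches
    ``min_jaccard``.
    """
    key = catalog["trait"].astype(str) + "|" + catalog["pubmed_id"].astype(str)
    bins: dict[str, set] = {}
    for k, sub in catalog.groupby(key.to_numpy()):
        bins[k] = set(zip(sub["chrom"], (sub["pos"].astype(np.int64) - 1) // bin_bp))
    keys = sorted(bins)
    rows = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = bins[keys[i]], bins[keys[j]]
            inter = len(a & b)
            union = len(a | b)
            jac = inter / union if union else 0.0
            if jac >= min_jaccard:
                rows.append((keys[i], keys[j], jac, inter))
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "jaccard", "n_shared_bins"])


def nearest_expressed_gene(hit_enhancers: pd.DataFrame, tss: pd.DataFrame,
                           expression: pd.DataFrame, group_samples: list[str],
                           floor: float = 2.0) -> pd.DataFrame:
    """Nearest expressed gene per lead-SNP enhancer.

    Genes with group-mean expression below ``floor`` (log2 FPKM) are
    excluded before the nearest-TSS search (distance from the enhancer
    midpoint; equidistant ties go to the lower TSS coordinate).
    """
    mean_expr = expression[group_samples].mean(axis=1)
    expressed = tss[tss["gene"].map(mean_expr) >= floor]
    mid = (hit_enhancers["start"].to_numpy() + hit_enhancers["end"].to_numpy()) // 2
    rows = []
    for (chrom, m, eid) in zip(hit_enhancers["chrom"], mid,
                               hit_enhancers["id"] if "id" in hit_enhancers
                               else hit_enhancers["name"]):
        sub = expressed[expressed["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no expressed gene on chromosome {chrom}")
        d = np.abs(sub["pos"].to_numpy() - m)
        best = np.lexsort((sub["pos"].to_numpy(), d))[0]
        rows.append((eid, sub["gene"].iloc[best], int(d[best])))
    return pd.DataFrame(rows, columns=["enhancer", "gene", "distance_bp"])


def geneset_overrepresentation(gene_list, gene_sets: dict[str, object],
                               background) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in gene sets."""
    background = set(background)
    if not background:
        raise ValueError("empty background")
    gene_list = set(gene_list)
    if not gene_list <= background:
        raise ValueError("gene list must be contained in the background")
    N, n = len(background), len(gene_list)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & background
        k = len(gene_list & members)
        rows.append((set_id, k, len(members), n, N, hypergeom_tail(k, N, len(members), n)))
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p_hyper"])
    table["p_bh"] = bh_adjust(table["p_hyper"])
    return table


def coassociation(focal_loci: pd.DataFrame, other_loci: pd.DataFrame,
                  node_enhancers: pd.DataFrame, radius_bp: int = 2_500,
                  overlap_bp: int = 2_500) -> float:
    """One-tailed Mann-Whitney co-association of two traits at a node.

    Focal-trait loci falling in the node's enhancers (2.5-kb midpoint
    rule) are split by whether they lie within ``overlap_bp`` of any
    locus of the other trait; the test asks whether in-overlap loci are
    more significant (greater ``neglogp``) than out-of-overlap ones.
    Returns the one-tailed p, or NaN when either side has < 2 loci.
    """
    hits = snp_enhancer_overlap(focal_loci.rename(columns={"neglogp": "_nl"}),
                                node_enhancers, radius_bp)
    in_node = focal_loci.loc[sorted(set(hits["snp_index"]))]
    if in_node.empty:
        return float("nan")
    other_pos = {c: np.sort(sub["pos"].to_numpy())
                 for c, sub in other_loci.groupby("chrom")}
    overlap = []
    for chrom, p in zip(in_node["chrom"], in_node["pos"]):
        arr = other_pos.get(chrom)
        if arr is None:
            overlap.append(False)
            continue
        i = np.searchsorted(arr, p)
        near = []
        if i < len(arr):
            near.append(arr[i] - p)
        if i > 0:
            near.append(p - arr[i - 1])
        overlap.append(bool(near and min(near) <= overlap_bp))
    overlap = np.asarray(overlap)
    a = in_node.loc[overlap, "neglogp"].to_numpy()
    b = in_node.loc[~overlap, "neglogp"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
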