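# enhancerkit

Analysis toolkit for enhancer-centric regulatory genomics on epigenomic
compendia: from per-biosample chromatin-state segmentations and binned
histone-mark signal tracks to enhancer modules, enhancer–gene links,
GWAS enrichments and trait–tissue interpretation.

It is aimed at computational biologists who work with large imputed /
observed epigenome collections (hundreds of biosamples, -log10 P signal
tracks at 200-bp resolution, 18-state ChromHMM-style segmentations) and
want a tested, reproducible implementation of the standard analysis
chain — including a seeded synthetic-compendium generator with planted
ground truth, so every stage can be validated by parameter recovery.

## What it computes

**Active enhancers.** A DHS-index element *d* is an active enhancer in
biosample *s* iff it overlaps an enhancer-state segment (E7–E11, E15)
of *s* and the width-weighted mean H3K27ac −log10 P over *d* ± 100 bp
exceeds 2. Elements are classified enhancer / promoter / dyadic by the
strict >75% rule on their active occurrences. The result is the binary
element × biosample **activity matrix** A.

**Enhancer modules.** A is clustered with Lloyd-style *k*-centroids
under the Jaccard distance d(x, c) = 1 − |x∧c| / |x∨c| (greedy
farthest-point initialisation, seeded restarts, deterministic
tie-breaks), with centre diagonalisation and hypergeometric metadata
enrichment of each module's included samples (centre > 0.25).

**Enhancer–gene links.** For every (enhancer, gene) pair within 1 Mb,
Pearson correlations between expression and per-mark enhancer signal
across shared biosamples, plus TSS distance, feed a gradient-boosted
tree classifier (XGBoost) trained against paired random
other-chromosome negatives; links with probability strictly above 5/7
are kept, per biosample and enhancer state.

**GWAS enrichment.** The association catalog is pruned greedily per
study (5-kb spacing by ascending p-value), HLA-filtered
(chr6:29,691,116–33,054,976), and power-filtered (≥10,000 samples, ≥10
lead SNPs). A SNP hits an enhancer when it lies within 2.5 kb of the
enhancer midpoint. Per (annotation set, study) the upper-tail
hypergeometric P(X ≥ k) is computed on unique-SNP counts
(X ~ HG(N, K, n)), BH-corrected as one family, with an empirical FDR
from 100 trait-shuffled catalogs. A complete-linkage tree over
biosamples (1 − Jaccard of enhancer sets) carries consensus enhancer
sets (subtree intersections); each node is tested on its differential
set (consensus minus parent consensus).

**Trait–tissue analysis.** Tree nodes get strict-majority tissue
labels; summed −log10 p per tissue gives the tissue × trait matrix
feeding trait classification (uni/multi/polyfactorial), tissue Jaccard
similarity with a fixed-marginal checkerboard-permutation null, a
cosine-distance (≤ 0.25) cross-trait network, and a genetic-overlap
network from shared 10-kb SNP bins.

**Track QC.** Observed-vs-imputed metrics (genome-wide r, top-1%-in-
top-5% peak recoveries, AUC), 5%-drop elbow flagging of ranked
correlations, residual-outlier detectors (3 robust SD) for sample
swaps, antibody swaps and secondary reactivities, and non-negative
quantile-rescaled delta tracks.

## Worked example

```python
from enhancerkit import synthdata as sd, enhancers as en, gwas as gw, traits as tr
from sklearn.metrics import adjusted_rand_score

cfg = sd.SynthConfig(seed=1, n_traits=10, marks=("H3K27ac",))
comp = sd.generate_compendium(cfg)
catalog = sd.generate_gwas_catalog(cfg, comp.truth)

k27 = {s: comp.observed[(s, "H3K27ac")] for s in comp.metadata["sample"]}
activity = en.call_active_enhancers(comp.dhs, comp.segmentations, k27)
modules = en.cluster_modules(activity, k=cfg.n_modules, seed=0)
pruned = gw.prune_catalog(catalog)
tree = gw.build_tree(activity)
table = gw.tree_enrichment(pruned, tree, activity.elements.rename(columns={"name": "id"}))
```

printed summary of this run:

```
1200 active enhancers across 40 biosamples (120 index elements never enhancer-active)
k=6 modules, mean Jaccard distance to centroid 0.153, ARI vs planted modules 1.00
pruned catalog: 591 of 600 associations kept
strongest trait-node enrichment: trait009|30000009 at node 35 (kidney), k=16/30 SNPs
in the tested set, p=8.77e-10, BH q=1.37e-06
```

Reading: the 1,200 planted enhancers are all recovered as active; the
120 promoter elements in the index are correctly rejected by the state
gate. Clustering at the true k reproduces the planted module labels
exactly (adjusted Rand index 1.0). After 5-kb pruning, the strongest
tree enrichment for trait009 — planted into kidney enhancers — lands
on a node whose subtree is pure kidney, with 16 of its 30 lead SNPs in
that node's differential enhancer set.

The full pipeline (simulate → qc → enhancers → modules → link → gwas →
traits) runs from one config and is byte-deterministic:

```sh
enhancerkit run --seed 1 --out results/run1
```

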