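# Methods

This note documents the models, default parameters, numerical choices
and limitations of `enhancerkit`. Everything quantitative stated here
is computed by the test suite or `scripts/acceptance.py`.

## Synthetic compendium

The generator (`synthdata`) emulates the inputs of the analysis chain
on a small synthetic genome (`chrS01…chrSk`, 200-bp bins; names chosen
so that coordinates can never collide with real assemblies — the HLA
filter only ever matches `chr6`).

**Layout.** Enhancer elements occupy one 200-bp bin each, placed on a
5.2-kb stride so that the 2.5-kb SNP-overlap windows of neighbouring
elements never overlap; the signal peak spans the element bin plus one
bin on each side, so the mean over the element ± 100 bp equals the peak
amplitude. Gene TSSs sit 600 bp from their host enhancer; short gene
bodies follow. Each mark additionally owns disjoint shared and
tissue-group-specific background domains, which give every mark
sample-group structure (needed for swap detection) without touching
enhancer windows.

**Modules and activity.** Enhancers belong to `n_modules` modules; one
module (12.5% by default, mirroring the broadly active fraction of
real compendia) is active in ≥77% of tissue groups, the rest in one
home group each (round-robin, so `n_modules ≥ n_tissue_groups`).
Realized activity of (enhancer, sample) is Bernoulli:
`module_activity_prob = 0.9` inside the module's groups, `leak_prob =
0.02` outside. Chromatin state, H3K27ac/H3K4me1 amplitude and
expression all follow the realized activity, so leaks are genuine
spurious active occurrences, not mere signal noise.

**Signal model.** Active bins draw amplitude 2 + Gamma(shape 2, scale
1.5); inactive bins draw Exponential(mean 0.5) *truncated below 2*.
The truncation makes activity-label noise governed solely by
`leak_prob`: in the noiseless limit (leak 0, activity probability 1,
`track_noise_sd` 0) re-deriving the activity matrix downstream is
exact, which the tests assert. Observed and imputed tracks share the
amplitude and add independent N(0, `track_noise_sd` = 0.25) noise
(clipped at 0); the residual activity-call error at defaults is ≈ 0.1%.
The true signal distribution of imputed tracks in real data is
unknown; these distributions are a documented stand-in and are
exposed in the config.

**Expression and links.** Each gene's expression equals the H3K27ac
amplitude of one host enhancer plus N(0, `expression_noise_sd` = 0.5),
on a log2-FPKM-like scale where active ≈ 5 and inactive ≈ 0.5 — so the
2.0 expression floor used for nearest-expressed-gene lookups separates
the two regimes.

**Catalog.** Each trait is assigned one tissue group; 80% of its 30
lead SNPs (defaults) are placed within 2.5 kb of midpoints of
enhancers whose module is active in that group, the rest uniformly.
P-values are log-uniform on [1e-30, 5e-8] and sample sizes ≥ 10,000,
so the power filters pass by construction. `background_snp_count`
becomes extra background-only studies that stabilise the catalog-wide
unique-SNP background N.

**Determinism.** Six RNG streams (layout, activity, signal,
expression, catalog, swaps) derive from the master seed with fixed
offsets; changing `n_traits` cannot perturb the signal tracks.
Identical configs produce byte-identical emitted files.

**Planted swaps.** Sample-swap pairs are drawn across tissue groups
and antibody-swap pairs across mark families (active / transcription /
repressive). Within-group or within-family swaps exchange
near-identical tracks and are undetectable in principle, so planting
them would measure nothing.

## Track QC

The four observed-vs-imputed metrics use rank-based top sets (top 1%
within top 5%, ties broken by genomic order) and an AUC of the imputed
signal ranking the top-1% observed bins. The elbow rule flags, on
descending ranked correlations, the first track whose drop from its
predecessor exceeds 5% of the predecessor, and everything below it
(the elbow point inclusive).

The three outlier detectors share one scheme: each track is summarised
by its average correlation to the 10 most similar imputed tracks of
every mark; per mark pair, a straight line of cross-mark vs same-mark
summaries is fitted across tracks, and residuals beyond 3 residual
scales flag a track, one-sided in the direction the anomaly lives
(cross-mark too high for antibody swaps/reactivities; own-sample
correlation too low for sample swaps). Two deliberate choices:

* **Theil–Sen line with MAD scale, not OLS.** A mislabeled track
  corrupts the predictor as well as the response — its same-mark
  correlation collapses while a cross-mark one rises — which hands it
  extreme leverage. An OLS line passes through such points and hides
  them entirely (observed empirically on planted swaps); the robust
  line does not, and the MAD keeps outliers out of the dispersion
  estimate.
* **Signature gate.** A flag additionally requires the raw-correlation
  swap signature (antibody: the track correlates better with the other
  mark than its putative one; sample: own-sample correlation below the
  top-10 average; reactivity: cross-mark correlation of the delta
  above 0.1). This is the automated analogue of the visual
  confirmation step practitioners apply after residual flagging and
  removes residual-only false positives: on clean 200-track synthetic
  compendia the detectors flag nothing, and all 8 planted swap tracks
  are recovered with ≤ 2 false positives.

Delta tracks quantile-match the imputed distribution onto the observed
one (rank for rank, deterministic ordinal ranks) before subtracting
and clipping at zero, so monotone intensity distortions — including
the general bias of observed tracks toward higher intensity — cancel
exactly.

## Enhancer calling and modules

Mean signal over the element ± 100 bp is a width-weighted mean of the
piecewise-constant binned track (windows clipped at chromosome ends);
activity requires a strict `> 2` on that mean plus overlap with an
enhancer-state segment. Element classification uses the strict
`> 75%` rule on per-biosample active occurrences; exactly 75% is
dyadic.

`JaccardKCentroids` keeps real-valued centres (within-cluster column
means, interpretable as activity frequencies) and thresholds them at
0.5 for the binary Jaccard distance (a real-valued min/max
generalisation is available behind `binary_centroids=False`).
Because the thresholded-mean update is not a guaranteed descent step
for the Jaccard objective, the iteration keeps the best assignment
seen and stops if an update fails to improve it — the reported
objective is therefore non-increasing. Ties in assignment break to the
lowest module index; empty clusters are re-seeded with the worst-fit
point; `n_init = 5` seeded restarts keep the best objective (a single
farthest-point initialisation occasionally merges two planted
modules). On the reference conditions (6 modules × 200 enhancers, 40
biosamples, 2% leak) recovery is ARI ≥ 0.9 across seeds, typically 1.0.

Diagonalisation puts columns with centre > 0.25 in more than half the
rows first, then sorts by argmax row, ties by column id. Metadata
enrichment includes samples with centre strictly above 0.25 and
reports entries with −log10 p > 2 by default.

## Enhancer–gene linking

Candidates pair enhancers and genes with |TSS − midpoint| ≤ 1 Mb
(boundary inclusive). Correlation features are Pearson r across the
biosamples shared by expression and signal; undefined correlations
(constant vectors) are recorded as 0 and flagged. Cross-chromosome
negatives reuse the paired positive's distance so the classifier
cannot separate the classes on distance alone. The classifier is
XGBoost with 500 trees, depth 4, learning rate 0.05, single-threaded
with a fixed seed for bit-reproducibility; probabilities are the raw
additive-logistic outputs, and the keep rule is strictly above 5/7.
Five active marks (H3K27ac, H3K4me1, H3K4me2, H3K4me3, H3K9ac) are the
nominal feature set; the synthetic compendium exercises H3K27ac and
H3K4me1, and any further mark can be added through the signal dict.

## GWAS enrichment

Pruning sorts each study by ascending p-value (ties by position) and
keeps a SNP iff it is more than 5,000 bp from every previously kept
SNP on the same chromosome; the HLA interval is removed first and the
power filters applied last. SNP positions are 1-based; BED midpoints
are converted to 1-based before the inclusive 2.5-kb midpoint rule.

All enrichment operations share one exact upper-tail hypergeometric
primitive, verified against integer binomial-coefficient arithmetic on
every 2×2 table with N ≤ 60 (max |error| < 1e-12). A SNP appearing in
several studies counts once in the background (K, N) and per study in
(k, n); BH correction treats all pairs of one run as a single family.

The empirical FDR permutes the study-label column globally across
association rows of the already-pruned catalog (positions fixed, study
sizes preserved) and reports mean shuffled significant count over real
significant count. Under a structure-free catalog the estimate is ≈ 1
(mean over 20 null seeds within [0.5, 2]); with zero real significant
pairs it is NaN with a warning. Note the exact tails are discrete,
hence conservative: the raw null exceedance rate at 0.05 is ≈ 0.03,
and calibration is checked on the randomized probability-integral
transform, which is exactly uniform under the null.

The biosample tree is a hand-rolled O(n³) complete-linkage
agglomeration over 1 − Jaccard of per-sample enhancer sets with a
documented deterministic tie-break (smallest original sample index);
it matches brute-force recomputation of cluster distances on every
random instance tested, and scipy's implementation serves as an
independent height oracle. Consensus sets are subtree intersections,
so each node's consensus is a superset of its parent's; node tests
default to the differential set (consensus minus parent consensus,
empty sets skipped), with the full-consensus variant behind
`tested="consensus"` since both readings exist in practice. Tested
sets along any root-to-leaf path are provably disjoint, which the
tests assert.

Rarefaction is greedy set cover where a set covers a trait if
significant for it, or — for traits with no significant set — if it
holds that trait's maximal enrichment; ties break to the smaller set
id.

## Trait-level analyses

Node tissue labels require a strict majority of subtree leaves
(exactly half is "multiple"). The tissue × trait matrix sums −log10 p
over each tissue's BH-significant nodes; the normalized variant scales
trait columns to sum 1. Trait classes: unifactorial = exactly one
enriched tissue, multifactorial ≥ 2, polyfactorial ≥ 10 (configurable;
the canonical definition of the polyfactorial cut is ambiguous, so it
is a parameter).

The permutation null holds the focal tissue's rows of the binary
node × trait matrix fixed and rewires the rest with 10 × (#ones)
checkerboard swap attempts per permutation; row and column marginals
are asserted invariant on every iteration. Empirical p = (1 + #{perm ≥
obs}) / (1 + n_perm) ∈ (0, 1]. A permutable block with no checkerboard
and non-constant entries yields NaN with a warning (a constant block
legitimately gives p = 1). The sampler is the standard swap chain; its
mixing is not formally verified, which is the usual caveat of
fixed-marginal permutation tests.

The cross-trait network links traits at cosine distance ≤ 0.25 of
their normalized tissue profiles, colours nodes/edges by argmax
tissue, and stores a seeded spring layout (presentation only, excluded
from correctness guarantees). The genetic network bins 1-based SNP
positions as (pos − 1) // 10,000 per chromosome and links trait pairs
with bin-set Jaccard ≥ 1% (the 5% variant is a parameter). The
locus-level co-association test ranks a focal trait's in-node loci by
proximity (≤ 2.5 kb) to another trait's loci and applies a one-tailed
Mann–Whitney test on locus significances; this construction is a
best-effort reading and is isolated in one function.

## Workflow

`run_pipeline` executes simulate → qc → enhancers → modules → link →
gwas → traits, writing plain-text artifacts and a manifest with
SHA-256 digests, parameters, seeds and collected warnings. All stage
seeds derive from one master seed; two runs from one configuration are
byte-identical (wall-clock runtimes live in a sidecar `runlog.json` so
the manifest itself is deterministic). In the pipeline the link
classifier trains on the generator's planted links; on real data the
positive set would come from the user's candidate links or gold
standards.

## Problem sizes and what passing tests show

The test suite runs the reference conditions at desk scale: 40
biosamples, 1,200 enhancers, ~6.5-Mb genome, 20–30 studies, 200 signal
tracks — sizes chosen so the whole suite completes in a few minutes on
one CPU. The synthetic compendium plants clean block structure with
homogeneous noise: it does not emulate LD between SNPs, mappability or
copy-number artifacts, correlated measurement noise between marks,
cell-type mixtures, or the heavy-tailed signal of real imputed tracks.
Passing recovery tests therefore demonstrates correctness of the
algorithms and their calibration under the stated generative model,
not performance on real compendia; thresholds carried from the
reference analysis (signal 2, 5/7, 5 kb, 2.5 kb, 0.25, 3 SD) are
defaults, not re-derived optima.
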