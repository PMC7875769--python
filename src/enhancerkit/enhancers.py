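"""Active-enhancer calling and Jaccard k-centroids module clustering.

An element of the DHS index is an *active enhancer* in a biosample when
it overlaps an enhancer-state segment (states E7-E11 or E15 of the
18-state model) of that sample's segmentation and the mean H3K27ac
-log10 P signal over the element +/- 100 bp exceeds 2.  The resulting
binary element x biosample matrix is the pipeline's central object; it
is clustered into modules with a Lloyd-style k-centroids algorithm
under the Jaccard distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from ._stats import bh_adjust, hypergeom_tail
from .tracks import SignalTrack, interval_overlap_mask

ENHANCER_STATES = frozenset({"E7", "E8", "E9", "E10", "E11", "E15"})
PROMOTER_STATES = frozenset({"E1", "E2", "E3", "E4", "E14"})
KNOWN_STATES = frozenset({f"E{i}" for i in range(1, 19)})


@dataclass
class ActivityMatrix:
    """Binary activity calls (and mean H3K27ac signal) per element x biosample."""

    elements: pd.DataFrame        # chrom,start,end,name of the retained elements
    samples: list[str]
    A: np.ndarray                 # bool, elements x samples
    S: np.ndarray | None = None   # mean signal over element +/- flank
    dropped: pd.DataFrame | None = None  # index rows never active in any sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A.astype(np.int8),
                            index=self.elements["name"].to_numpy(), columns=self.samples)

    def signal_frame(self) -> pd.DataFrame:
        if self.S is None:
            raise ValueError("no signal matrix present")
        return pd.DataFrame(self.S, index=self.elements["name"].to_numpy(), columns=self.samples)


@dataclass
class ModuleSet:
    """Result of clustering elements into k activity modules."""

    k: int
    assignment: pd.Series         # element -> module index
    centers: pd.DataFrame         # module x biosample mean activity in [0, 1]
    objective: float              # mean Jaccard distance to assigned centroid


def binarization_cutoff(observed, imputed, obs_cutoff: float = 2.0) -> float:
    """Imputed-track cutoff at the observed exceedance quantile of ``obs_cutoff``.

    Returns the smallest imputed value whose empirical CDF reaches the
    observed CDF at ``obs_cutoff`` — i.e. the imputed-distribution
    quantile matched to the fraction of observed values above the
    observed cutoff.
    """
    observed = np.asarray(observed, dtype=float)
    imputed = np.asarray(imputed, dtype=float)
    if observed.size == 0 or imputed.size == 0:
        raise ValueError("both distributions must be non-empty")
    q = float(np.mean(observed > obs_cutoff))
    return float(np.quantile(imputed, 1.0 - q, method="inverted_cdf"))


def call_active_elements(
    dhs: pd.DataFrame,
    segmentations: dict[str, pd.DataFrame],
    signal: dict[str, SignalTrack],
    states: frozenset[str] = ENHANCER_STATES,
    signal_threshold: float = 2.0,
    flank_bp: int = 100,
    drop_inactive: bool = True,
) -> ActivityMatrix:
    """Call per-biosample element activity from states and signal.

    ``A[d, s]`` is 1 iff DHS ``d`` overlaps a segment of ``s`` whose
    state is in ``states`` and the width-weighted mean signal over
    ``[start - flank, end + flank)`` in ``s`` strictly exceeds the
    threshold.  ``S`` stores the mean signal.  Rows never active in any
    sample are dropped (reported on ``dropped``) unless
    ``drop_inactive=False``.
    """
    samples = sorted(segmentations)
    for s in samples:
        if s not in signal:
            raise ValueError(f"no signal track for sample {s}")
    dhs = dhs.reset_index(drop=True)
    n = len(dhs)
    A = np.zeros((n, len(samples)), dtype=bool)
    S = np.zeros((n, len(samples)))
    for si, s in enumerate(samples):
        seg = segmentations[s]
        unknown = set(seg["state"]) - KNOWN_STATES
        if unknown:
            raise ValueError(f"unknown state mnemonics in sample {s}: {sorted(unknown)}")
        track = signal[s]
        for chrom, sub in dhs.groupby("chrom", sort=False):
            if chrom not in track.data:
                raise ValueError(f"DHS on undeclared chromosome {chrom}")
            seg_c = seg[(seg["chrom"] == chrom) & seg["state"].isin(states)]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            in_state = interval_overlap_mask(seg_c, starts, ends)
            means = track.windowed_mean(chrom, starts - flank_bp, ends + flank_bp)
            S[sub.index, si] = means
            A[sub.index, si] = in_state & (means > signal_threshold)
    keep = A.any(axis=1) if drop_inactive else np.ones(n, dtype=bool)
    dropped = dhs.loc[~keep].reset_index(drop=True)
    return ActivityMatrix(
        elements=dhs.loc[keep].reset_index(drop=True),
        samples=samples, A=A[keep], S=S[keep], dropped=dropped,
    )


def call_active_enhancers(dhs, segmentations, h3k27ac_tracks,
                          enhancer_states: frozenset[str] = ENHANCER_STATES,
                          signal_threshold: float = 2.0,
                          flank_bp: int = 100) -> ActivityMatrix:
    """Active-enhancer calls: enhancer-state overlap AND mean H3K27ac > 2."""
    return call_active_elements(dhs, segmentations, h3k27ac_tracks,
                                states=enhancer_states,
                                signal_threshold=signal_threshold, flank_bp=flank_bp)


def classify_elements(enhancer_occurrences, promoter_occurrences) -> pd.Series:
    """Classify elements as enhancer / promoter / dyadic by active occurrences.

    An element is an enhancer (promoter) when strictly more than 75% of
    its active occurrences carry that annotation; otherwise dyadic.
    """
    e = np.asarray(enhancer_occurrences, dtype=float)
    p = np.asarray(promoter_occurrences, dtype=float)
    if np.any(e < 0) or np.any(p < 0):
        raise ValueError("occurrence counts must be non-negative")
    total = e + p
    if np.any(total == 0):
        raise ValueError("elements with zero active occurrences cannot be classified")
    out = np.where(e / total > 0.75, "enhancer",
                   np.where(p / total > 0.75, "promoter", "dyadic"))
    index = enhancer_occurrences.index if isinstance(enhancer_occurrences, pd.Series) else None
    return pd.Series(out, index=index, name="element_class")


# --------------------------------------------------------------------------
# Jaccard k-centroids


def jaccard_distance_matrix(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise Jaccard distance between binary rows of X and of C.

    ``d(x, c) = 1 - |x & c| / |x | c|``; two empty rows are at distance 0.
    """
    X = np.asarray(X, dtype=bool)
    C = np.asarray(C, dtype=bool)
    inter = X.astype(np.float64) @ C.T.astype(np.float64)
    union = X.sum(axis=1)[:, None] + C.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    return d


class JaccardKCentroids(BaseEstimator, ClusterMixin):
    """Lloyd-style k-centroids clustering of a binary matrix under Jaccard distance.

    Initialisation is greedy farthest-point (k-means++-style) from a
    seeded random first pick; ``n_init`` restarts are run and the
    solution with the lowest objective kept.  Centroids are maintained as within-cluster
    column means; for distance evaluation they are thresholded to binary
    at 0.5 by default (``binary_centroids=False`` uses a real-valued
    Jaccard generalisation with min/max in place of and/or).  Iteration
    stops when assignments are stable, the objective (mean Jaccard
    distance to the assigned centroid) improves by less than ``tol``, or
    an update fails to improve it — the reported objective is therefore
    non-increasing over iterations.  Assignment ties break to the lowest
    module index.

    Attributes (after ``fit``): ``labels_``, ``cluster_centers_`` (mean
    activity per cluster), ``objective_``, ``inertia_``, ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 300, max_iter: int = 100, tol: float = 1e-6,
                 random_state: int | None = None, binary_centroids: bool = True,
                 n_init: int = 5):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.binary_centroids = binary_centroids
        self.n_init = n_init

    def _distances(self, X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        if self.binary_centroids:
            return jaccard_distance_matrix(X, centers >= 0.5)
        Xf = X.astype(np.float64)
        inter = Xf @ centers.T  # x binary: sum of min(x, c) = sum of c where x=1
        union = Xf.sum(1)[:, None] + centers.sum(1)[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - inter / union
        d[union == 0] = 0.0
        return d

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.size == 0:
            raise ValueError("X must be a non-empty 2D binary matrix")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be binary")
        X = X.astype(bool)
        distinct = np.unique(X, axis=0)
        if self.n_clusters > len(distinct):
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds {len(distinct)} distinct rows")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            labels, obj, centers, n_iter = self._fit_once(X, rng)
            if best is None or obj < best[1]:
                best = (labels, obj, centers, n_iter)
        labels, best_obj, centers, n_iter = best
        self.labels_ = labels
        self.cluster_centers_ = np.vstack([
            X[labels == j].mean(axis=0) if np.any(labels == j) else centers[j]
            for j in range(self.n_clusters)
        ])
        self.objective_ = best_obj
        self.inertia_ = best_obj * len(X)
        self.n_iter_ = n_iter
        return self

    def _fit_once(self, X: np.ndarray, rng: np.random.Generator):
        centers = self._init_centers(X, rng)
        labels = None
        best_obj = np.inf
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            d = self._distances(X, centers)
            new_labels = d.argmin(axis=1)
            obj = float(d[np.arange(len(X)), new_labels].mean())
            if obj > best_obj + 1e-15:  # thresholded-mean update is not a
                n_iter -= 1             # guaranteed descent step: keep the best
                break
            improved = best_obj - obj
            labels, best_obj = new_labels, obj
            new_centers = self._update_centers(X, labels, centers, d)
            if improved < self.tol and n_iter > 1:
                centers = new_centers
                break
            centers = new_centers
        return labels, best_obj, centers, n_iter

    def _init_centers(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        first = int(rng.integers(0, len(X)))
        chosen = [first]
        mind = jaccard_distance_matrix(X, X[[first]])[:, 0]
        while len(chosen) < self.n_clusters:
            nxt = int(np.argmax(mind))  # argmax ties -> lowest index
            chosen.append(nxt)
            mind = np.minimum(mind, jaccard_distance_matrix(X, X[[nxt]])[:, 0])
        return X[chosen].astype(np.float64)

    def _update_centers(self, X, labels, centers, d) -> np.ndarray:
        new = centers.copy()
        for j in range(self.n_clusters):
            members = labels == j
            if members.any():
                new[j] = X[members].mean(axis=0)
            else:  # re-seed an empty cluster with the worst-fit point
                new[j] = X[int(np.argmax(d.min(axis=1)))]
        return new

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        X = np.asarray(X).astype(bool)
        return self._distances(X, self.cluster_centers_).argmin(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_modules(activity, k: int, seed: int | None = 0, max_iter: int = 100,
                    tol: float = 1e-6, binary_centroids: bool = True) -> ModuleSet:
    """Cluster the binary activity matrix into ``k`` enhancer modules."""
    if isinstance(activity, ActivityMatrix):
        frame = activity.to_frame()
    else:
        frame = pd.DataFrame(activity)
    model = JaccardKCentroids(n_clusters=k, max_iter=max_iter, tol=tol,
                              random_state=seed, binary_centroids=binary_centroids)
    model.fit(frame.to_numpy())
    centers = pd.DataFrame(model.cluster_centers_, columns=frame.columns,
                           index=pd.RangeIndex(k, name="module"))
    return ModuleSet(
        k=k,
        assignment=pd.Series(model.labels_, index=frame.index, name="module"),
        centers=centers,
        objective=model.objective_,
    )


def diagonalize(centers: pd.DataFrame, broad_value: float = 0.25,
                broad_row_frac: float = 0.5) -> list:
    """Column order for a diagonalised heat map of module centres.

    ``centers`` has biosamples as rows and modules as columns.  Columns
    with value > ``broad_value`` in strictly more than ``broad_row_frac``
    of rows come first (the broadly active block, in column order); the
    rest are sorted by the row index of their maximal value, ties broken
    by column id.
    """
    broad = (centers > broad_value).mean(axis=0) > broad_row_frac
    broad_cols = [c for c in centers.columns if broad[c]]
    rest = [c for c in centers.columns if not broad[c]]
    argmax = {c: int(np.argmax(centers[c].to_numpy())) for c in rest}
    rest.sort(key=lambda c: (argmax[c], str(c)))
    return broad_cols + rest


def metadata_enrichment(modules: ModuleSet, metadata: pd.DataFrame,
                        inclusion_threshold: float = 0.25,
                        report_neglogp: float | None = 2.0,
                        columns: list[str] | None = None) -> pd.DataFrame:
    """Hypergeometric enrichment of metadata labels among module samples.

    A biosample is *included* in a module when its centre value strictly
    exceeds ``inclusion_threshold``.  Per (module, metadata label) the
    upper-tail hypergeometric p compares the label count among included
    samples with its overall frequency.  Only entries with
    ``-log10 p > report_neglogp`` are returned (pass ``None`` for all).
    """
    md = metadata.set_index("sample") if "sample" in metadata.columns else metadata
    missing = set(modules.centers.columns) - set(md.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    md = md.loc[list(modules.centers.columns)]
    columns = columns or [c for c in md.columns if md[c].dtype == object]
    N = len(md)
    rows = []
    for module, center in modules.centers.iterrows():
        included = center.index[center.to_numpy() > inclusion_threshold]
        if len(included) == 0:
            warnings.warn(f"module {module}: empty inclusion set, no enrichments")
            continue
        n = len(included)
        for col in columns:
            for label, K in md[col].value_counts().items():
                k = int((md.loc[included, col] == label).sum())
                p = hypergeom_tail(k, N, int(K), n)
                rows.append((module, col, label, k, int(K), n, N, p))
    table = pd.DataFrame(rows, columns=["module", "field", "label", "k", "K", "n", "N", "p_hyper"])
    if report_neglogp is not None and len(table):
        table = table[-np.log10(table["p_hyper"].clip(lower=1e-300)) > report_neglogp]
    return table.reset_index(drop=True)
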