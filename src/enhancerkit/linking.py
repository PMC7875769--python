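"""Enhancer-gene link prediction from correlation and distance features.

Candidate links pair every enhancer with every gene whose TSS lies
within 1 Mb; features are the per-mark Pearson correlation between gene
expression and enhancer signal across the biosamples shared by the
expression matrix and the signal matrices, plus the (absolute) distance
to the TSS.  A paired negative per positive re-samples the gene from a
different chromosome while reusing the positive's distance, so the
classifier cannot separate the classes on distance alone.  A
gradient-boosted tree classifier scores candidates and links with
probability strictly above 5/7 are kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

KEEP_THRESHOLD = 5.0 / 7.0


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between each row of X and the vector y; constants give r=0."""
    xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum(axis=1))
    sy = np.sqrt((yc * yc).sum())
    flat = (sx == 0) | (sy == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.where(flat, 0.0, r)
    return r, flat


def candidate_correlations(
    expression: pd.DataFrame,
    signal: dict[str, pd.DataFrame],
    tss: pd.DataFrame,
    enhancers: pd.DataFrame,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Correlation features for every (enhancer, gene) pair within the window.

    ``expression``: genes x samples; ``signal``: mark -> enhancers x
    samples real-valued activity; ``tss``: columns gene/chrom/pos;
    ``enhancers``: BED-like with id.  Pairs are included when the
    absolute midpoint-to-TSS distance is <= ``window_bp``.  Undefined
    correlations (constant vectors) are recorded as 0 with
    ``constant_flag`` set.
    """
    marks = sorted(signal)
    shared = set(expression.columns)
    for m in marks:
        shared &= set(signal[m].columns)
    shared = sorted(shared)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared biosamples between expression and signal")
    expr = expression[shared]
    sig = {m: signal[m].loc[:, shared] for m in marks}
    mid = (enhancers["start"].to_numpy() + enhancers["end"].to_numpy()) // 2
    enh = enhancers.assign(mid=mid)

    rows = []
    for chrom, genes_c in tss.groupby("chrom", sort=True):
        enh_c = enh[enh["chrom"] == chrom]
        if enh_c.empty:
            continue
        order = np.argsort(enh_c["mid"].to_numpy(), kind="stable")
        emid = enh_c["mid"].to_numpy()[order]
        eids = enh_c["id"].to_numpy()[order]
        for gene, gpos in zip(genes_c["gene"], genes_c["pos"]):
            lo = np.searchsorted(emid, gpos - window_bp, side="left")
            hi = np.searchsorted(emid, gpos + window_bp, side="right")
            for j in range(lo, hi):
                rows.append((eids[j], gene, int(gpos - emid[j])))
    table = pd.DataFrame(rows, columns=["enhancer", "gene", "distance_bp"])
    if table.empty:
        return table
    return _attach_correlations(table, expr, sig)


def _attach_correlations(table: pd.DataFrame, expr: pd.DataFrame,
                         sig: dict[str, pd.DataFrame]) -> pd.DataFrame:
    marks = sorted(sig)
    out = table.copy()
    flags = np.zeros(len(table), dtype=bool)
    for m in marks:
        out[f"r_{m}"] = 0.0
    for gene, sub in table.groupby("gene", sort=False):
        y = expr.loc[gene].to_numpy(dtype=float)
        for m in marks:
            X = sig[m].loc[sub["enhancer"]].to_numpy(dtype=float)
            r, flat = _pearson_rows(X, y)
            out.loc[sub.index, f"r_{m}"] = r
            flags[sub.index] |= flat
    out["constant_flag"] = flags
    return out


def make_negatives(candidates: pd.DataFrame, expression: pd.DataFrame,
                   signal: dict[str, pd.DataFrame], tss: pd.DataFrame,
                   seed: int = 0) -> pd.DataFrame:
    """One paired negative per candidate: same enhancer, random other-chromosome gene.

    The negative reuses the positive's distance feature; correlations
    are recomputed for the sampled gene.
    """
    gene_chrom = tss.set_index("gene")["chrom"]
    if gene_chrom.nunique() < 2:
        raise ValueError("negatives require genes on at least 2 chromosomes")
    cand_chrom = candidates["gene"].map(gene_chrom)
    rng = np.random.default_rng(seed)
    genes = gene_chrom.index.to_numpy()
    neg_gene = np.empty(len(candidates), dtype=object)
    for chrom in cand_chrom.unique():
        pool = genes[(gene_chrom != chrom).to_numpy()]
        if len(pool) == 0:
            raise ValueError(f"no genes outside chromosome {chrom}")
        idx = np.flatnonzero((cand_chrom == chrom).to_numpy())
        neg_gene[idx] = pool[rng.integers(0, len(pool), size=len(idx))]
    shared = sorted(set(expression.columns) & set.intersection(
        *(set(signal[m].columns) for m in signal)))
    table = pd.DataFrame({
        "enhancer": candidates["enhancer"].to_numpy(),
        "gene": neg_gene,
        "distance_bp": candidates["distance_bp"].to_numpy(),
    })
    return _attach_correlations(table, expression[shared],
                                {m: signal[m].loc[:, shared] for m in sorted(signal)})


def _feature_matrix(table: pd.DataFrame, feature_cols: list[str]) -> np.ndarray:
    X = table[[c for c in feature_cols if c != "abs_distance"]].to_numpy(dtype=float)
    if "abs_distance" in feature_cols:
        X = np.column_stack([X, np.abs(table["distance_bp"].to_numpy(dtype=float))])
    return X


class LinkClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted trees over per-mark correlations and TSS distance.

    Thin scikit-learn-style wrapper around :class:`xgboost.XGBClassifier`
    (500 trees, depth 4, learning rate 0.05 by default; single-threaded
    for reproducibility).  Probabilities are the model's additive
    logistic output without recalibration.
    """

    def __init__(self, n_estimators: int = 500, max_depth: int = 4,
                 learning_rate: float = 0.05, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training requires both positive and negative examples")
        self.model_ = XGBClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, random_state=self.random_state,
            n_jobs=1, tree_method="hist", eval_metric="logloss",
        )
        self.model_.fit(np.asarray(X, dtype=float), y)
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.predict_proba(X)[:, 1] >= 0.5


def train_link_classifier(positives: pd.DataFrame, negatives: pd.DataFrame,
                          seed: int = 0, feature_cols: list[str] | None = None
                          ) -> tuple[LinkClassifier, list[str]]:
    """Fit the link classifier on paired positive/negative candidate tables."""
    if feature_cols is None:
        feature_cols = sorted(c for c in positives.columns if c.startswith("r_"))
        feature_cols.append("abs_distance")
    X = np.vstack([_feature_matrix(positives, feature_cols),
                   _feature_matrix(negatives, feature_cols)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])
    clf = LinkClassifier(random_state=seed)
    clf.fit(X, y)
    return clf, feature_cols


def predict_links(clf: LinkClassifier, feature_cols: list[str],
                  candidates: pd.DataFrame, activity,
                  states: pd.Series | None = None,
                  threshold: float = KEEP_THRESHOLD) -> pd.DataFrame:
    """Score candidates and emit per-(enhancer, gene, biosample, state) links.

    A row is emitted only where the enhancer is active in the biosample;
    ``kept`` is True iff probability strictly exceeds the threshold
    (probability exactly at the threshold is not kept).
    """
    prob = clf.predict_proba(_feature_matrix(candidates, feature_cols))[:, 1]
    act = activity.to_frame() if hasattr(activity, "to_frame") else pd.DataFrame(activity)
    rows = []
    for (enh, gene, p) in zip(candidates["enhancer"], candidates["gene"], prob):
        if enh not in act.index:
            continue
        state = states.get(enh, "NA") if states is not None else "NA"
        for s in act.columns[act.loc[enh].to_numpy(dtype=bool)]:
            rows.append((enh, gene, s, state, float(p), bool(p > threshold)))
    return pd.DataFrame(rows, columns=["enhancer", "gene", "biosample", "state",
                                       "probability", "kept"])


def evaluate_links(predictions: dict[str, object], gold_positives: set,
                   gold_negatives: set) -> pd.DataFrame:
    """Precision / recall / F1 per method against a gold standard of pairs.

    Each method maps to either a set of kept (enhancer, gene) pairs, or a
    score table (columns enhancer/gene/score) for threshold-free
    baselines, where each enhancer contributes only its highest-scoring
    gene as its single positive call.  Precision counts only calls that
    are in the gold positive or negative set; empty call sets report
    precision 0 with ``undefined_precision`` flagged.
    """
    if not gold_positives:
        raise ValueError("empty gold-standard positive set")
    rows = []
    for method, pred in predictions.items():
        if isinstance(pred, pd.DataFrame):
            best = pred.sort_values(["score", "gene"], ascending=[False, True],
                                    kind="stable").groupby("enhancer", sort=False).head(1)
            calls = set(zip(best["enhancer"], best["gene"]))
        else:
            calls = set(pred)
        tp = len(calls & gold_positives)
        fp = len(calls & gold_negatives)
        fn = len(gold_positives - calls)
        undefined = (tp + fp) == 0
        precision = 0.0 if undefined else tp / (tp + fp)
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        rows.append((method, tp, fp, fn, precision, recall, f1, undefined))
    return pd.DataFrame(rows, columns=["method", "tp", "fp", "fn", "precision",
                                       "recall", "f1", "undefined_precision"])
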