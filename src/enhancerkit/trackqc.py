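"""Quality control of observed vs imputed signal tracks.

Implements the four classic imputation QC metrics (genome-wide
correlation, observed/imputed peak recovery, AUC), elbow-based
low-quality flagging on ranked correlations, regression-residual
detectors for sample swaps, antibody swaps and secondary antibody
reactivities, and delta-track construction.

The swap detectors share one scheme: summarise every observed track by
its average correlation to the 10 most similar imputed tracks of each
mark, fit a leverage-resistant straight line per mark pair across tracks,
and flag residual outliers beyond ``n_sd`` residual scales on the side
the anomaly lives on (cross-mark correlation too high for antibody
swaps and reactivities; own-sample correlation too low for sample
swaps), requiring in addition the corresponding swap signature in the
raw correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .tracks import SignalTrack


@dataclass(frozen=True)
class QcMetrics:
    """Observed-vs-imputed agreement summaries for one track pair."""

    genomewide_correlation: float
    peak_recovery_obs: float  # % of top-1% observed bins inside top-5% imputed bins
    peak_recovery_imp: float  # % of top-1% imputed bins inside top-5% observed bins
    auc: float                # AUC of imputed signal ranking top-1% observed bins


def _top_bins(values: np.ndarray, frac: float) -> np.ndarray:
    """Indices of the top ``frac`` bins by signal; ties broken by genomic order."""
    n = len(values)
    k = max(1, int(n * frac))
    order = np.lexsort((np.arange(n), -values))
    return order[:k]


def qc_metrics(observed: SignalTrack, imputed: SignalTrack,
               top_frac: float = 0.01, within_frac: float = 0.05) -> QcMetrics:
    """Compute all four QC metrics for an (observed, imputed) track pair."""
    if not observed.same_binning(imputed):
        raise ValueError("observed and imputed tracks must share binning and chromosomes")
    o, i = observed.values(), imputed.values()
    if np.ptp(o) == 0 or np.ptp(i) == 0:
        raise ValueError("correlation undefined for an all-constant track")
    r = float(np.corrcoef(o, i)[0, 1])
    top_o, top_i = _top_bins(o, top_frac), _top_bins(i, top_frac)
    wide_o, wide_i = set(_top_bins(o, within_frac)), set(_top_bins(i, within_frac))
    rec_obs = 100.0 * sum(b in wide_i for b in top_o) / len(top_o)
    rec_imp = 100.0 * sum(b in wide_o for b in top_i) / len(top_i)
    labels = np.zeros(len(o), dtype=int)
    labels[top_o] = 1
    auc = float(roc_auc_score(labels, i))
    return QcMetrics(r, rec_obs, rec_imp, auc)


def flag_low_quality(metric_by_track: dict[str, float]) -> list[str]:
    """Elbow rule on ranked correlations.

    Tracks are sorted descending; the elbow is the first rank ``i`` where
    the drop from rank ``i-1`` exceeds 5% of the rank ``i-1`` value.  The
    elbow track and everything below it are flagged; no elbow, no flags.
    """
    if len(metric_by_track) < 3:
        raise ValueError("need at least 3 tracks to locate an elbow")
    items = sorted(metric_by_track.items(), key=lambda kv: (-kv[1], kv[0]))
    values = np.array([v for _, v in items])
    drops = values[:-1] - values[1:]
    elbow = np.flatnonzero(drops > 0.05 * values[:-1])
    if len(elbow) == 0:
        return []
    return [k for k, _ in items[elbow[0] + 1:]]


# --------------------------------------------------------------------------
# Swap and reactivity detectors


def _corr_matrix(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Pearson correlations between every row of ``rows`` and of ``cols``."""
    a = rows - rows.mean(axis=1, keepdims=True)
    b = cols - cols.mean(axis=1, keepdims=True)
    sa = np.sqrt((a * a).sum(axis=1))
    sb = np.sqrt((b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (a @ b.T) / np.outer(sa, sb)
    return c


def _top_k_mean(corrs: np.ndarray, k: int = 10) -> np.ndarray:
    """Mean of the k largest entries per row (all entries if fewer)."""
    if corrs.shape[1] == 0:
        return np.full(corrs.shape[0], np.nan)
    kk = min(k, corrs.shape[1])
    part = np.sort(corrs, axis=1)[:, -kk:]
    return part.mean(axis=1)


def _avg_top10_by_mark(tracks: dict[tuple, SignalTrack],
                       imputed: dict[tuple, SignalTrack],
                       top_k: int = 10) -> tuple[list[tuple], list[str], np.ndarray]:
    """avg top-k correlation of each track to imputed tracks of each mark."""
    keys = sorted(tracks)
    marks = sorted({m for (_, m) in imputed})
    mat = np.vstack([tracks[k].values() for k in keys])
    out = np.zeros((len(keys), len(marks)))
    for j, m in enumerate(marks):
        ikeys = [k for k in sorted(imputed) if k[1] == m]
        if len(ikeys) < top_k:
            warnings.warn(f"mark {m}: only {len(ikeys)} imputed tracks, using all")
        imat = np.vstack([imputed[k].values() for k in ikeys])
        out[:, j] = _top_k_mean(_corr_matrix(mat, imat), top_k)
    return keys, marks, out


def _line_residuals(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Residuals from a robust straight-line fit, with a robust scale.

    A mislabeled track corrupts the predictor as well as the response
    (its same-mark correlation collapses while a cross-mark one rises),
    handing it extreme leverage; an ordinary least-squares line would
    pass through such points and hide them.  A Theil-Sen line with a
    MAD-based residual scale keeps outliers out of both the fit and the
    dispersion estimate.
    """
    if np.ptp(x) < 1e-12:
        resid = y - np.median(y)
    else:
        fit = stats.theilslopes(y, x)
        resid = y - (fit.intercept + fit.slope * x)
    scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return resid, scale


def _flag_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["track_id", "kind", "score_sd", "statistic", "details"])


def detect_antibody_swaps(observed: dict[tuple, SignalTrack],
                          imputed: dict[tuple, SignalTrack],
                          n_sd: float = 3.0, top_k: int = 10,
                          min_cross_corr: float = -1.0,
                          kind: str = "antibody_swap") -> pd.DataFrame:
    """Flag tracks whose cross-mark correlation is anomalously high.

    For each putative mark m and every other mark m', fit a straight
    line of the average top-10 correlation to imputed m' tracks against
    the average top-10 correlation to imputed m tracks, across all
    observed tracks labeled m.  A track is flagged when its residual
    exceeds ``n_sd`` residual scales *and* it shows the swap signature —
    it correlates better with the other mark than with its putative one
    (and at least ``min_cross_corr``, which callers can raise to demand
    non-trivial resemblance).
    """
    keys, marks, avg = _avg_top10_by_mark(observed, imputed, top_k)
    rows: list[dict] = []
    for mi, m in enumerate(marks):
        idx = [i for i, k in enumerate(keys) if k[1] == m]
        if len(idx) < 3:
            continue
        x = avg[idx, mi]
        for mj, m2 in enumerate(marks):
            if m2 == m:
                continue
            y = avg[idx, mj]
            resid, sd = _line_residuals(x, y)
            if sd < 1e-12:
                warnings.warn(f"degenerate residuals for mark pair ({m}, {m2}); no flags")
                continue
            for pos, r in zip(idx, resid):
                if r > n_sd * sd and avg[pos, mj] > max(avg[pos, mi], min_cross_corr):
                    s, _ = keys[pos]
                    rows.append({"track_id": f"{s}:{m}", "kind": kind,
                                 "score_sd": r / sd, "statistic": f"resid_vs_{m2}",
                                 "details": f"cross={avg[pos, mj]:.3f} same={avg[pos, mi]:.3f}"})
    return _flag_frame(rows)


def detect_sample_swaps(observed: dict[tuple, SignalTrack],
                        imputed: dict[tuple, SignalTrack],
                        n_sd: float = 3.0, top_k: int = 10) -> pd.DataFrame:
    """Flag tracks whose own-sample imputed correlation is anomalously low.

    Per mark, regress the correlation of each observed track with its
    own sample's imputed track on the average top-10 correlation within
    the mark; residuals below ``-n_sd`` standard deviations flag a
    potential sample swap.
    """
    keys, marks, avg = _avg_top10_by_mark(observed, imputed, top_k)
    rows: list[dict] = []
    for mi, m in enumerate(marks):
        idx = [i for i, k in enumerate(keys) if k[1] == m and k in imputed]
        skipped = [k for k in keys if k[1] == m and k not in imputed]
        for k in skipped:
            warnings.warn(f"no own-sample imputed track for {k[0]}:{k[1]}; skipped")
        if len(idx) < 3:
            continue
        own = np.array([
            _corr_matrix(observed[keys[i]].values()[None, :],
                         imputed[keys[i]].values()[None, :])[0, 0]
            for i in idx
        ])
        x = avg[idx, mi]
        resid, sd = _line_residuals(x, own)
        if sd < 1e-12:
            warnings.warn(f"degenerate residuals for mark {m}; no flags")
            continue
        for pos, r, o in zip(idx, resid, own):
            if r < -n_sd * sd and o < avg[pos, mi]:
                s, _ = keys[pos]
                rows.append({"track_id": f"{s}:{m}", "kind": "sample_swap",
                             "score_sd": r / sd, "statistic": "own_vs_top10",
                             "details": f"own={o:.3f} top10={avg[pos, mi]:.3f}"})
    return _flag_frame(rows)


def delta_track(observed: SignalTrack, imputed: SignalTrack) -> SignalTrack:
    """Non-negative excess of observed over intensity-rescaled imputed signal.

    The imputed values are quantile-matched onto the observed
    distribution (rank for rank), which removes monotone intensity
    distortions; the per-bin difference is clipped at 0 because the
    target is excess observed signal (reactivity).
    """
    if not observed.same_binning(imputed):
        raise ValueError("tracks must share binning and chromosomes")
    o, i = observed.values(), imputed.values()
    sorted_o = np.sort(o)
    ranks = stats.rankdata(i, method="ordinal").astype(int) - 1
    rescaled = sorted_o[ranks]
    delta = np.clip(o - rescaled, 0.0, None)
    data: dict[str, np.ndarray] = {}
    off = 0
    for c in observed.chroms:
        n = len(observed.data[c])
        data[c] = delta[off:off + n]
        off += n
    return SignalTrack(observed.sample, observed.mark, observed.bin_bp, data)


def detect_secondary_reactivity(deltas: dict[tuple, SignalTrack],
                                imputed: dict[tuple, SignalTrack],
                                n_sd: float = 3.0, top_k: int = 10,
                                min_cross_corr: float = 0.1) -> pd.DataFrame:
    """Flag delta tracks that look like a primary track of another mark.

    Same regression scheme as antibody-swap detection, with the delta
    tracks in place of the observed tracks.  All-zero deltas are skipped
    with a warning (their correlation is undefined).
    """
    usable = {}
    for k, t in deltas.items():
        if np.ptp(t.values()) == 0:
            warnings.warn(f"delta track {k[0]}:{k[1]} is constant; skipped")
            continue
        usable[k] = t
    if not usable:
        return _flag_frame([])
    return detect_antibody_swaps(usable, imputed, n_sd=n_sd, top_k=top_k,
                                 min_cross_corr=min_cross_corr,
                                 kind="secondary_reactivity")


def restricted_correlation(track_a: SignalTrack, track_b: SignalTrack,
                           mask: np.ndarray, method: str = "pearson") -> float:
    """Correlation of two tracks over a boolean bin mask (genomic order)."""
    if not track_a.same_binning(track_b):
        raise ValueError("tracks must share binning and chromosomes")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("mask must select at least 3 bins")
    a, b = track_a.values()[mask], track_b.values()[mask]
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method: {method}")
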