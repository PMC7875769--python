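"""Fixed-bin signal tracks and BED/bedGraph input-output.

A :class:`SignalTrack` stores a -log10 P signal as one vector of
fixed-width bins per chromosome.  Genomic order is the lexicographic
chromosome order followed by bin index; every routine that flattens a
track to a single vector uses that order so ranks and masks line up
across tracks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass
class SignalTrack:
    """Binned -log10 P signal for one (biosample, mark) pair."""

    sample: str
    mark: str
    bin_bp: int
    data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, v in self.data.items():
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{self.track_id}:{chrom}: signal must be finite and >= 0")
            self.data[chrom] = v

    @property
    def track_id(self) -> str:
        return f"{self.sample}:{self.mark}"

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)

    def values(self) -> np.ndarray:
        """All bins concatenated in genomic order."""
        return np.concatenate([self.data[c] for c in self.chroms])

    def same_binning(self, other: "SignalTrack") -> bool:
        return (
            self.bin_bp == other.bin_bp
            and self.chroms == other.chroms
            and all(self.data[c].shape == other.data[c].shape for c in self.chroms)
        )

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom]) * self.bin_bp

    def windowed_mean(self, chrom: str, starts, ends) -> np.ndarray:
        """Width-weighted mean signal over half-open windows ``[start, end)``.

        The signal is treated as piecewise constant over bins; partial
        bin overlaps contribute proportionally to their covered width.
        Windows are clipped to the chromosome.
        """
        v = self.data[chrom]
        starts = np.clip(np.asarray(starts, dtype=np.int64), 0, len(v) * self.bin_bp)
        ends = np.clip(np.asarray(ends, dtype=np.int64), 0, len(v) * self.bin_bp)
        if np.any(ends <= starts):
            raise ValueError("windows must have positive clipped width")
        # cumulative integral of the step function at bin boundaries
        cum = np.concatenate([[0.0], np.cumsum(v) * self.bin_bp])

        def integral(x):
            b = x // self.bin_bp
            frac = x - b * self.bin_bp
            b = np.minimum(b, len(v) - 1)
            return cum[b] + v[b] * frac

        return (integral(ends) - integral(starts)) / (ends - starts)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                v = self.data[chrom]
                for i, x in enumerate(v):
                    fh.write(f"{chrom}\t{i * self.bin_bp}\t{(i + 1) * self.bin_bp}\t{x:.4f}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, sample: str, mark: str, bin_bp: int
    ) -> "SignalTrack":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
        data: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            if not np.all((sub["end"] - sub["start"]) == bin_bp):
                raise ValueError(f"{path}: bins are not uniformly {bin_bp} bp on {chrom}")
            n = int(sub["end"].max() // bin_bp)
            v = np.zeros(n)
            v[(sub["start"] // bin_bp).to_numpy()] = sub["value"].to_numpy()
            data[str(chrom)] = v
        return cls(sample=sample, mark=mark, bin_bp=bin_bp, data=data)


def stack_tracks(tracks: Iterable[SignalTrack]) -> tuple[list[str], np.ndarray]:
    """Stack tracks into an (n_tracks, n_bins) matrix in genomic order."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no tracks given")
    ref = tracks[0]
    for t in tracks[1:]:
        if not t.same_binning(ref):
            raise ValueError(f"track {t.track_id} binning differs from {ref.track_id}")
    ids = [t.track_id for t in tracks]
    return ids, np.vstack([t.values() for t in tracks])


# --------------------------------------------------------------------------
# BED-style tables


def read_bed(path: str | Path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path, columns=("chrom", "start", "end", "name")) -> None:
    cols = [c for c in columns if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def midpoints(intervals: pd.DataFrame) -> np.ndarray:
    """0-based midpoints ``floor((start + end) / 2)`` of BED intervals."""
    return ((intervals["start"].to_numpy() + intervals["end"].to_numpy()) // 2).astype(np.int64)


def interval_overlap_mask(
    segments: pd.DataFrame, query_starts: np.ndarray, query_ends: np.ndarray
) -> np.ndarray:
    """For each query window, whether any segment overlaps it.

    ``segments`` is a BED-like frame for a single chromosome.  Works for
    arbitrary (possibly overlapping, unsorted) segment sets via a sorted
    cumulative-max sweep.
    """
    if len(segments) == 0:
        return np.zeros(len(query_starts), dtype=bool)
    order = np.argsort(segments["start"].to_numpy(), kind="stable")
    starts = segments["start"].to_numpy()[order]
    ends = segments["end"].to_numpy()[order]
    cummax_end = np.maximum.accumulate(ends)
    idx = np.searchsorted(starts, query_ends, side="left")
    out = np.zeros(len(query_starts), dtype=bool)
    nz = idx > 0
    out[nz] = cummax_end[idx[nz] - 1] > query_starts[nz]
    return out


def radius_hits(
    points_a: Mapping[str, np.ndarray] | pd.DataFrame,
    points_b: pd.DataFrame,
    radius: int,
) -> pd.DataFrame:
    """All pairs ``(a, b)`` on the same chromosome with ``|pos_a - pos_b| <= radius``.

    ``points_a`` needs columns ``chrom``/``pos``; ``points_b`` columns
    ``chrom``/``pos`` plus an ``id`` carried into the output.
    """
    if isinstance(points_a, pd.DataFrame):
        a = points_a
    else:
        a = pd.DataFrame(points_a)
    rows = []
    for chrom, sub_b in points_b.groupby("chrom", sort=True):
        sub_a = a[a["chrom"] == chrom]
        if sub_a.empty:
            continue
        order = np.argsort(sub_b["pos"].to_numpy(), kind="stable")
        bpos = sub_b["pos"].to_numpy()[order]
        bid = sub_b["id"].to_numpy()[order]
        lo = np.searchsorted(bpos, sub_a["pos"].to_numpy() - radius, side="left")
        hi = np.searchsorted(bpos, sub_a["pos"].to_numpy() + radius, side="right")
        for (ai, apos), l, h in zip(sub_a[["pos"]].itertuples(name=None), lo, hi):
            for j in range(l, h):
                rows.append((ai, chrom, apos, bid[j], bpos[j]))
    return pd.DataFrame(rows, columns=["a_index", "chrom", "pos", "b_id", "b_pos"])
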