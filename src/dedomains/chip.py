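"""ChIP signal preprocessing: median scaling, quantile normalization, 1-kb
binning, TSS-window scores and the developmental relative-position statistic.

The array-processing order follows the tiling-array workflow: per-channel
median scaling to a common target, quantile normalization across channels,
replicate averaging, then smoothing to fixed-width bins by the mean probe
score per bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genome import FeatureSet, Genome
from .tracks import BinnedTrack, ProbeTrack

__all__ = [
    "quantile_normalize",
    "scale_median",
    "bin_track",
    "average_tracks",
    "tss_window_median",
    "relative_class_position",
]

MEDIAN_TARGET = 500.0  # per-channel median intensity target
TSS_HALF_WIDTH = 500  # bp, symmetric window around the TSS


def quantile_normalize(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Quantile-normalize equal-length score vectors to a common distribution.

    The reference distribution is the mean of order statistics across
    inputs; each output is the rank-preserving rearrangement of that
    reference, with tied values receiving the mean reference value of
    their tied ranks.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("vectors must have equal length")
    if any(np.isnan(a).any() for a in arrs):
        raise ValueError("missing values must be masked before normalization")
    reference = np.mean([np.sort(a) for a in arrs], axis=0)
    out = []
    for a in arrs:
        # fractional average ranks handle ties: interpolate into the
        # sorted reference at rank-1 positions
        ranks = rankdata(a, method="average") - 1.0
        out.append(np.interp(ranks, np.arange(n), reference))
    return out


def scale_median(vector: np.ndarray, target: float = MEDIAN_TARGET) -> np.ndarray:
    """Multiplicatively scale a positive-median vector so its median is ``target``."""
    vector = np.asarray(vector, dtype=float)
    if vector.size == 0:
        raise ValueError("empty vector")
    med = float(np.median(vector))
    if med <= 0:
        raise ValueError(f"median must be positive, got {med}")
    return vector * (target / med)


def average_tracks(tracks: list[ProbeTrack]) -> ProbeTrack:
    """Average replicate probe tracks sharing the same probe layout."""
    if not tracks:
        raise ValueError("no tracks")
    base = tracks[0]
    stacked = np.mean([t.df["score"].to_numpy(dtype=float) for t in tracks], axis=0)
    df = base.df.copy()
    df["score"] = stacked
    return ProbeTrack(base.genome, df)


def bin_track(probes: ProbeTrack, bin_width: int) -> BinnedTrack:
    """Smooth a probe track to fixed-width bins: mean probe score per bin.

    A probe is assigned to the bin containing its interval midpoint; bins
    with no probes are missing (NaN), never zero.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    genome = probes.genome
    scores: dict[str, np.ndarray] = {}
    for chrom in probes.df["chrom"].unique():
        chrom = str(chrom)
        sub = probes.on(chrom)
        n = genome.n_bins(chrom, bin_width)
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        idx = np.minimum(mid // bin_width, n - 1)
        sums = np.bincount(idx, weights=sub["score"].to_numpy(dtype=float), minlength=n)
        counts = np.bincount(idx, minlength=n)
        with np.errstate(invalid="ignore"):
            vec = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        scores[chrom] = vec
    return BinnedTrack(genome, bin_width, scores)


def tss_window_median(
    track: ProbeTrack | BinnedTrack,
    features: FeatureSet,
    half_width: int = TSS_HALF_WIDTH,
) -> pd.DataFrame:
    """Median signal in a symmetric window around each feature position.

    For probe tracks the median is over probes overlapping
    ``[pos - half_width, pos + half_width)``; for binned tracks, over
    non-missing bins overlapping the window. Features with no covered
    score get NaN. Returns a table with columns chrom, pos, label, score.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    rows = []
    for row in features.df.itertuples(index=False):
        lo, hi = row.pos - half_width, row.pos + half_width
        if isinstance(track, ProbeTrack):
            sub = track.on(row.chrom)
            sel = sub[(sub["end"] > lo) & (sub["start"] < hi)]
            vals = sel["score"].to_numpy(dtype=float)
        else:
            vec = track.scores.get(row.chrom)
            if vec is None:
                vals = np.array([])
            else:
                b0 = max(lo // track.bin_width, 0)
                b1 = min(-(-hi // track.bin_width), len(vec))
                vals = vec[b0:b1]
                vals = vals[~np.isnan(vals)]
        score = float(np.median(vals)) if vals.size else np.nan
        rows.append((row.chrom, row.pos, row.label, score))
    return pd.DataFrame(rows, columns=["chrom", "pos", "label", "score"])


def relative_class_position(mean_hk: float, mean_pc: float, mean_x: float) -> float:
    """Position of a class mean on the scale anchored at 0 = housekeeping
    mean and 1 = Polycomb-target mean."""
    if mean_pc == mean_hk:
        raise ValueError("anchor means are equal; scale undefined")
    return (mean_x - mean_hk) / (mean_pc - mean_hk)
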