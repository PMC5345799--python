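"""Distance-resolved interaction statistics and D-D corner hotspot detection.

Three analyses on normalized contact matrices:

* per-bin short-range (5-50 kb) vs long-range (50-500 kb) interaction
  fractions at 5-kb resolution, with chromosome-end and extreme-coverage
  exclusions;
* per-domain-label median normalized count per 10-kb distance bin with a
  two-sided rank-sum comparison of the D and E per-distance medians;
* detection of D-D corner hotspots atop E-domain blocks: the rectangle
  coupling the two flanking D domains is compared, at matched interaction
  distance, with genomic-shifted rectangles of the same shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import DomainMap
from .hic import ContactMatrix
from .simulate import eligible_e_domains

logger = logging.getLogger("dedomains")

__all__ = [
    "distance_fraction_profile",
    "domain_distance_profile",
    "detect_dd_hotspots",
]

SHORT_RANGE = (5_000, 50_000)
LONG_RANGE = (50_000, 500_000)
MAX_DISTANCE = 1_000_000
END_EXCLUSION = 1_000_000
HIGH_PERCENTILE = 97.5
MIN_E_LENGTH = 60_000
FOLD_THRESHOLD = 1.1
MAX_FLANK_BINS = 10


def distance_fraction_profile(
    matrix: ContactMatrix,
    short_range: tuple[int, int] = SHORT_RANGE,
    long_range: tuple[int, int] = LONG_RANGE,
    max_distance: int = MAX_DISTANCE,
    end_exclusion: int = END_EXCLUSION,
    high_percentile: float = HIGH_PERCENTILE,
    total_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-anchor-bin short- and long-range interaction fractions.

    For each anchor bin, interactions to partners within ``max_distance``
    on both sides are collected and the vector normalized to sum 1; the
    short fraction is the mass at distances within ``short_range``
    (inclusive, so self-interactions below its lower edge are ignored)
    and the long fraction the mass in ``long_range`` (lower edge
    exclusive). Anchors within ``end_exclusion`` of either chromosome
    end, anchors with zero total, and anchors whose raw total exceeds
    the ``high_percentile`` of totals are excluded (mask column False).
    ``total_threshold`` overrides the percentile cut with a genome-wide
    precomputed threshold. Columns: bin, total, short, long, ratio, kept.
    """
    res = matrix.resolution
    n = matrix.n_bins
    v = matrix.values
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) * res
    in_range = dist <= max_distance  # distance-0 self counts stay in the total
    totals = np.where(in_range, v, 0.0).sum(axis=1)
    end_bins = end_exclusion // res
    kept = np.ones(n, dtype=bool)
    if end_bins > 0:
        kept[:end_bins] = False
        kept[n - end_bins :] = False
    kept &= totals > 0
    kept &= matrix.valid
    if total_threshold is None:
        pool = totals[kept]
        total_threshold = np.percentile(pool, high_percentile) if pool.size else np.inf
    kept &= totals <= total_threshold
    short_mask = (dist >= short_range[0]) & (dist <= short_range[1])
    long_mask = (dist > long_range[0]) & (dist <= long_range[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        short = np.where(short_mask & in_range, v, 0.0).sum(axis=1) / totals
        long = np.where(long_mask & in_range, v, 0.0).sum(axis=1) / totals
        ratio = short / long
    short[~kept] = np.nan
    long[~kept] = np.nan
    ratio[~kept | (long == 0)] = np.nan
    return pd.DataFrame(
        {
            "bin": np.arange(n),
            "total": totals,
            "short": short,
            "long": long,
            "ratio": ratio,
            "kept": kept,
        }
    )


def domain_distance_profile(
    matrix: ContactMatrix,
    dmap: DomainMap,
    min_length: int = 30_000,
) -> tuple[pd.DataFrame, float]:
    """Median normalized count per distance bin, separately for D and E.

    For each domain of the matrix's chromosome longer than ``min_length``,
    normalized values of bin pairs lying entirely inside the domain are
    collected by distance (in resolution units); the per-label median per
    distance bin is computed and the two labels' per-distance medians
    compared with a two-sided rank-sum test. Returns (table, p-value).
    """
    res = matrix.resolution
    if min_length < res:
        raise ValueError("min_length must be >= matrix resolution")
    per_label: dict[str, dict[int, list[np.ndarray]]] = {"D": {}, "E": {}}
    n_doms = {"D": 0, "E": 0}
    for dom in dmap.on(matrix.chrom):
        if dom.label not in ("D", "E") or len(dom) <= min_length:
            continue
        b0 = -(-dom.start // res)  # first bin fully inside
        b1 = dom.end // res  # one past last bin fully inside
        if b1 - b0 < 2:
            continue
        n_doms[dom.label] += 1
        sub = matrix.values[b0:b1, b0:b1]
        valid = matrix.valid[b0:b1]
        m = b1 - b0
        for d in range(1, m):
            vals = np.diagonal(sub, offset=d)
            ok = valid[:-d] & valid[d:]
            if ok.any():
                per_label[dom.label].setdefault(d, []).append(vals[ok])
    for label in ("D", "E"):
        if n_doms[label] == 0:
            raise ValueError(f"no {label} domains longer than {min_length} bp")
    rows = []
    med = {"D": {}, "E": {}}
    for label in ("D", "E"):
        for d, chunks in sorted(per_label[label].items()):
            med[label][d] = float(np.median(np.concatenate(chunks)))
            rows.append(
                {"label": label, "distance": d * res, "median": med[label][d]}
            )
    common = sorted(set(med["D"]) & set(med["E"]))
    if common:
        stat = stats.ranksums(
            [med["D"][d] for d in common], [med["E"][d] for d in common]
        )
        pvalue = float(stat.pvalue)
    else:
        pvalue = float("nan")
    logger.info(
        "domain_distance_profile: %d D / %d E domains, p=%.3g",
        n_doms["D"], n_doms["E"], pvalue,
    )
    return pd.DataFrame(rows), pvalue


@dataclass
class HotspotCall:
    chrom: str
    e_start: int
    e_end: int
    eligible: bool
    corner_density: float
    neighbour_density: float
    is_hotspot: bool


def _rect_mean(v: np.ndarray, valid: np.ndarray, r0, r1, c0, c1) -> float:
    n = v.shape[0]
    r0, r1 = max(r0, 0), min(r1, n)
    c0, c1 = max(c0, 0), min(c1, n)
    if r1 <= r0 or c1 <= c0:
        return np.nan
    block = v[r0:r1, c0:c1]
    w = np.outer(valid[r0:r1], valid[c0:c1])
    if not w.any():
        return np.nan
    return float(block[w].mean())


def _distance_normalized(matrix: ContactMatrix) -> np.ndarray:
    """Matrix divided by the genome-wide mean value at each interaction
    distance, removing distance decay so rectangles at different
    distances are comparable."""
    v = matrix.values
    n = matrix.n_bins
    valid2 = np.outer(matrix.valid, matrix.valid)
    out = np.ones_like(v)
    means = np.empty(n)
    for d in range(n):
        vals = np.diagonal(v, offset=d)
        ok = np.diagonal(valid2, offset=d)
        means[d] = vals[ok].mean() if ok.any() else np.nan
    # fall back to the nearest informative distance
    last = np.nanmean(means[np.isfinite(means) & (means > 0)])
    for d in range(n):
        if not np.isfinite(means[d]) or means[d] <= 0:
            means[d] = last
        else:
            last = means[d]
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    out = v / means[dist]
    return out


def _corner_rect(
    ivs, k: int, res: int, max_flank_bins: int
) -> tuple[int, int, int, int]:
    """Bin rectangle coupling the two D flanks of E domain ivs[k]:
    rows = left-flank D bins, cols = right-flank D bins, each truncated to
    ``max_flank_bins`` next to the E domain."""
    iv, left, right = ivs[k], ivs[k - 1], ivs[k + 1]
    r1 = iv.start // res
    r0 = max(left.start // res, r1 - max_flank_bins)
    c0 = -(-iv.end // res)
    c1 = min(-(-right.end // res), c0 + max_flank_bins)
    return r0, r1, c0, c1


def detect_dd_hotspots(
    matrix: ContactMatrix,
    dmap: DomainMap,
    min_e_length: int = MIN_E_LENGTH,
    fold_threshold: float = FOLD_THRESHOLD,
    max_flank_bins: int = MAX_FLANK_BINS,
    neighbour_mode: str = "corners",
    n_neighbours: int = 2,
    trim_factor: float = 1.5,
) -> pd.DataFrame:
    """Flag D-D interaction hotspots above E-domain blocks.

    Eligible E domains are >= ``min_e_length`` with D domains immediately
    adjacent on both sides (a separating gap disqualifies). The corner
    rectangle couples the left-flank D bins with the right-flank D bins
    (each side truncated to ``max_flank_bins`` next to the E domain).
    Densities are measured on the distance-normalized matrix (values
    divided by the genome-wide mean at each interaction distance), which
    removes distance-decay differences between rectangles.

    Neighbour density (``neighbour_mode``):

    * ``"corners"`` (default): the corner rectangles of the nearest
      eligible E domains on either side (up to ``n_neighbours`` per side)
      - the only regions matching the corner in domain composition, since
      coverage-product normalization leaves composition-dependent level
      differences. Candidates above ``trim_factor`` x the smallest
      candidate are dropped as likely hotspots themselves; the rest are
      averaged.
    * ``"shifted"``: same-shape rectangles shifted along the genome by one
      rectangle extent left and right at the same interaction distance.
    * ``"ring"``: one-bin ring around the corner rectangle.

    Hotspot when corner > fold_threshold x neighbour.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    res = matrix.resolution
    valid = matrix.valid
    vhat = _distance_normalized(matrix)
    ivs = dmap.on(matrix.chrom)
    eligible_idx = [k for k, _ in eligible_e_domains(dmap, matrix.chrom)]
    qualifying = [
        k for k in eligible_idx if len(ivs[k]) >= min_e_length
    ]
    corner_density = {
        k: _rect_mean(vhat, valid, *_corner_rect(ivs, k, res, max_flank_bins))
        for k in qualifying
    }
    finite = [c for c in corner_density.values() if np.isfinite(c)]
    global_corner = float(np.median(finite)) if finite else np.nan
    rows: list[HotspotCall] = []
    for k, iv in enumerate(ivs):
        if iv.label != "E":
            continue
        if k not in corner_density:
            rows.append(
                HotspotCall(iv.chrom, iv.start, iv.end, False, np.nan, np.nan, False)
            )
            continue
        corner = corner_density[k]
        r0, r1, c0, c1 = _corner_rect(ivs, k, res, max_flank_bins)
        if neighbour_mode == "corners":
            pos = qualifying.index(k)
            cand_idx = (
                qualifying[max(pos - n_neighbours, 0) : pos]
                + qualifying[pos + 1 : pos + 1 + n_neighbours]
            )
            cands = [
                corner_density[j] for j in cand_idx if np.isfinite(corner_density[j])
            ]
            if cands:
                lo = min(cands)
                kept = [c for c in cands if c <= trim_factor * lo]
                # guard against a locally low estimate: floor at the
                # genome-wide typical corner density (median is robust to
                # the hotspot-bearing minority)
                neigh = max(float(np.mean(kept)), global_corner)
            elif np.isfinite(global_corner):
                neigh = global_corner
            else:
                neigh = np.nan
        elif neighbour_mode == "shifted":
            shift = max(r1 - r0, c1 - c0)
            n1 = _rect_mean(vhat, valid, r0 - shift, r1 - shift, c0 - shift, c1 - shift)
            n2 = _rect_mean(vhat, valid, r0 + shift, r1 + shift, c0 + shift, c1 + shift)
            neigh = float(np.nanmean([n1, n2])) if np.isfinite([n1, n2]).any() else np.nan
        elif neighbour_mode == "ring":
            ring_vals = []
            for rr0, rr1, cc0, cc1 in (
                (r0 - 1, r0, c0 - 1, c1 + 1),
                (r1, r1 + 1, c0 - 1, c1 + 1),
                (r0, r1, c0 - 1, c0),
                (r0, r1, c1, c1 + 1),
            ):
                m = _rect_mean(vhat, valid, rr0, rr1, cc0, cc1)
                if np.isfinite(m):
                    ring_vals.append(m)
            neigh = float(np.mean(ring_vals)) if ring_vals else np.nan
        else:
            raise ValueError(f"unknown neighbour_mode {neighbour_mode!r}")
        is_hot = bool(
            np.isfinite(corner) and np.isfinite(neigh) and corner > fold_threshold * neigh
        )
        rows.append(
            HotspotCall(iv.chrom, iv.start, iv.end, True, corner, neigh, is_hot)
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if len(df):
        n_el = int(df["eligible"].sum())
        n_hot = int(df["is_hotspot"].sum())
        logger.info(
            "detect_dd_hotspots: %d eligible E domains, %d hotspots (%.0f%%)",
            n_el, n_hot, 100.0 * n_hot / n_el if n_el else 0.0,
        )
    return df
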