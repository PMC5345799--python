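"""Scaled-domain tile profiles, accumulation profiles and band overlays.

Domains of varying length are made comparable by splitting each into a
fixed number of tiles (default 80) extended by flank tiles of the same
width (default 10 per side); summit counts per tile are summed across
domains of the same label and scaled by 1000/n, with n the class's total
genome-wide summit count, so classes of different abundance plot on a
common scale. Flank tiles may overlap neighbouring domains; no exclusion
is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .boundaries import BorderSet
from .genome import DomainMap, FeatureSet, Genome, Interval

logger = logging.getLogger("dedomains")

__all__ = [
    "scaled_tile_profile",
    "tile_presence_matrix",
    "accumulation_profile",
    "scaled_interval_overlay",
]

N_TILES = 80
N_FLANK = 10
SUMMIT_SCALE = 1000.0  # per-class counts are multiplied by 1000/n


def _domain_tile_counts(
    positions: np.ndarray, dom: Interval, n_tiles: int, n_flank: int
) -> np.ndarray | None:
    """Raw per-tile counts for one domain; None when the domain is shorter
    than n_tiles bp (tile width < 1 bp)."""
    if len(dom) < n_tiles:
        return None
    width = len(dom) / n_tiles
    total = n_tiles + 2 * n_flank
    rel = (positions - dom.start) / width
    tiles = np.floor(rel).astype(int)
    inside = (positions >= dom.start) & (positions < dom.end)
    tiles[inside] = np.clip(tiles[inside], 0, n_tiles - 1)
    idx = tiles + n_flank
    counts = np.zeros(total)
    keep = (idx >= 0) & (idx < total)
    np.add.at(counts, idx[keep], 1)
    return counts


def scaled_tile_profile(
    features: FeatureSet,
    dmap: DomainMap,
    n_tiles: int = N_TILES,
    n_flank: int = N_FLANK,
) -> pd.DataFrame:
    """Summit counts on scaled domains, per domain label and feature class.

    Columns: domain, class, tile (0..n_tiles+2*n_flank-1, flanks at the
    edges), count (raw summed) and scaled (count x 1000/n with n the
    class's genome-wide total). Domains shorter than n_tiles bp are
    skipped with a logged count.
    """
    if n_tiles <= 0:
        raise ValueError("n_tiles must be positive")
    if n_flank < 0:
        raise ValueError("n_flank must be >= 0")
    total = n_tiles + 2 * n_flank
    classes = features.classes() or ["all"]
    rows = []
    for cls in classes:
        sub = features.subset(cls) if features.classes() else features
        n_total = len(sub)
        pos_by_chrom = {
            str(c): sub.positions(str(c)) for c in sub.df["chrom"].unique()
        }
        for dom_label in ("D", "E"):
            counts = np.zeros(total)
            n_skipped = 0
            for dom in dmap.domains(dom_label):
                pos = pos_by_chrom.get(dom.chrom)
                if pos is None:
                    continue
                c = _domain_tile_counts(pos, dom, n_tiles, n_flank)
                if c is None:
                    n_skipped += 1
                    continue
                counts += c
            if n_skipped:
                logger.info(
                    "scaled_tile_profile: %d %s domains shorter than %d bp skipped",
                    n_skipped, dom_label, n_tiles,
                )
            scale = SUMMIT_SCALE / n_total if n_total else 0.0
            for t in range(total):
                rows.append(
                    {
                        "domain": dom_label,
                        "class": cls,
                        "tile": t,
                        "count": counts[t],
                        "scaled": counts[t] * scale,
                    }
                )
    return pd.DataFrame(rows)


def tile_presence_matrix(
    features: FeatureSet,
    dmap: DomainMap,
    dom_label: str,
    n_tiles: int = N_TILES,
    n_flank: int = N_FLANK,
) -> np.ndarray:
    """Per-domain binary presence/absence of features per tile (stacked
    scaled-domain plot): rows are domains of ``dom_label``, columns tiles."""
    pos_by_chrom = {
        str(c): features.positions(str(c)) for c in features.df["chrom"].unique()
    }
    out = []
    for dom in dmap.domains(dom_label):
        pos = pos_by_chrom.get(dom.chrom, np.array([], dtype=np.int64))
        c = _domain_tile_counts(pos, dom, n_tiles, n_flank)
        if c is not None:
            out.append((c > 0).astype(int))
    return np.array(out) if out else np.empty((0, n_tiles + 2 * n_flank), dtype=int)


def accumulation_profile(
    features: FeatureSet,
    anchors: FeatureSet | BorderSet,
    window: int,
    bin_width: int,
    rescale: bool = True,
) -> pd.DataFrame:
    """Feature counts per offset bin around a set of anchors.

    Counts are scaled by 1000/n (n = total features), divided by the
    number of anchors, then affinely rescaled so the profile spans 0-10
    (min to 0, max to 10) unless ``rescale`` is off. Columns: offset
    (bin center, bp), count (raw), normalized (pre-rescale), scaled.
    """
    if window <= 0 or bin_width <= 0:
        raise ValueError("window and bin_width must be positive")
    if isinstance(anchors, BorderSet):
        anchor_pos = {c: np.asarray(p, dtype=float) for c, p in anchors.positions.items()}
    else:
        anchor_pos = {
            str(c): anchors.positions(str(c)).astype(float)
            for c in anchors.df["chrom"].unique()
        }
    n_anchors = sum(len(v) for v in anchor_pos.values())
    if n_anchors == 0:
        raise ValueError("zero anchors")
    n_bins = 2 * window // bin_width
    counts = np.zeros(n_bins)
    n_features = len(features)
    for chrom, apos in anchor_pos.items():
        fpos = features.positions(chrom).astype(float)
        if len(fpos) == 0 or len(apos) == 0:
            continue
        # offsets of every feature relative to every anchor on this chromosome
        offs = fpos[None, :] - apos[:, None]
        sel = (offs >= -window) & (offs < window)
        idx = ((offs[sel] + window) // bin_width).astype(int)
        np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1)
    normalized = counts * (SUMMIT_SCALE / n_features if n_features else 0.0) / n_anchors
    if rescale:
        lo, hi = normalized.min(), normalized.max()
        scaled = (
            (normalized - lo) / (hi - lo) * 10.0 if hi > lo else np.zeros_like(normalized)
        )
    else:
        scaled = normalized.copy()
    offsets = -window + bin_width * (np.arange(n_bins) + 0.5)
    return pd.DataFrame(
        {"offset": offsets, "count": counts, "normalized": normalized, "scaled": scaled}
    )


def scaled_interval_overlay(
    dmap: DomainMap,
    bands: list[Interval],
    genome: Genome,
    target_length: int = 200_000,
    flank: int = 50_000,
    min_length: int = 75_000,
    step: int = 1000,
) -> pd.DataFrame:
    """D/E occupancy along bands rescaled to a common length.

    Bands longer than ``min_length`` are linearly rescaled to
    ``target_length`` with unscaled flanks appended; at each sampled
    position the fraction of bands covered by D, E or neither is
    computed. Positions off the chromosome count as unassigned. Columns:
    position (bp on the scaled axis, 0 = band start), frac_d, frac_e,
    frac_gap.
    """
    kept = [iv for iv in bands if len(iv) > min_length]
    if not kept:
        raise ValueError("no bands pass the length filter")
    grid = np.arange(-flank, target_length + flank, step, dtype=float)
    tally = {k: np.zeros(len(grid)) for k in ("D", "E", None)}
    for band in kept:
        length = genome.length(band.chrom)
        gpos = np.empty(len(grid))
        left = grid < 0
        interior = (grid >= 0) & (grid < target_length)
        right = grid >= target_length
        gpos[left] = band.start + grid[left]
        gpos[interior] = band.start + grid[interior] / target_length * len(band)
        gpos[right] = band.end + (grid[right] - target_length)
        labels = np.full(len(grid), None, dtype=object)
        inside = (gpos >= 0) & (gpos < length)
        labels[inside] = dmap.label_at(band.chrom, gpos[inside])
        for k in tally:
            tally[k] += labels == k
    n = len(kept)
    return pd.DataFrame(
        {
            "position": grid,
            "frac_d": tally["D"] / n,
            "frac_e": tally["E"] / n,
            "frac_gap": tally[None] / n,
        }
    )
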