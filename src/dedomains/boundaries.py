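"""Distance statistics between two border sets (D/E vs TAD, D/E vs bands)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import DomainMap, Interval

logger = logging.getLogger("dedomains")

__all__ = [
    "BorderSet",
    "nearest_border_distances",
    "fraction_within",
    "distance_histogram",
]


@dataclass
class BorderSet:
    """Chromosome-wise sorted, deduplicated border positions in bp."""

    positions: dict[str, np.ndarray]
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = {
            c: np.unique(np.asarray(p, dtype=float))
            for c, p in self.positions.items()
        }

    def __len__(self) -> int:
        return sum(len(p) for p in self.positions.values())

    @classmethod
    def from_domain_map(
        cls, dmap: DomainMap, source: str = "D/E", include_ends: bool = False
    ) -> "BorderSet":
        return cls(
            {c: dmap.borders(c, include_ends=include_ends) for c in dmap.chromosomes()},
            source,
        )

    @classmethod
    def from_intervals(
        cls,
        intervals: list[Interval],
        source: str = "",
        genome=None,
        include_ends: bool = False,
    ) -> "BorderSet":
        """Interval edges as borders; chromosome-end edges (position 0 or
        chromosome length) are excluded unless ``include_ends``."""
        pos: dict[str, list[float]] = {}
        for iv in intervals:
            for p in (iv.start, iv.end):
                if not include_ends and genome is not None:
                    if p == 0 or p == genome.length(iv.chrom):
                        continue
                elif not include_ends and p == 0:
                    continue
                pos.setdefault(iv.chrom, []).append(float(p))
        return cls({c: np.array(v) for c, v in pos.items()}, source)

    @classmethod
    def from_boundary_bins(
        cls, boundaries: list[int], chrom: str, resolution: int, source: str = "TAD"
    ) -> "BorderSet":
        return cls({chrom: np.array([b * resolution for b in boundaries], dtype=float)}, source)


def nearest_border_distances(query: BorderSet, reference: BorderSet) -> np.ndarray:
    """Per query border, the minimum |distance| to any reference border on
    the same chromosome. Query borders on chromosomes absent from the
    reference are skipped (counted in the log)."""
    out: list[np.ndarray] = []
    n_skipped = 0
    for chrom, qpos in query.positions.items():
        rpos = reference.positions.get(chrom)
        if rpos is None or len(rpos) == 0:
            n_skipped += len(qpos)
            continue
        idx = np.searchsorted(rpos, qpos)
        left = rpos[np.clip(idx - 1, 0, len(rpos) - 1)]
        right = rpos[np.clip(idx, 0, len(rpos) - 1)]
        out.append(np.minimum(np.abs(qpos - left), np.abs(qpos - right)))
    if n_skipped:
        logger.info("nearest_border_distances: %d query borders skipped", n_skipped)
    return np.concatenate(out) if out else np.array([])


def fraction_within(distances: np.ndarray, tolerance: float) -> float:
    """Fraction of distances <= tolerance ("within one 10 kb bin" means
    tolerance = 10,000 bp)."""
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValueError("empty distance list")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return float(np.mean(distances <= tolerance))


def distance_histogram(
    distances: np.ndarray, bin_width: float, max_distance: float
) -> np.ndarray:
    """Counts per half-open distance bin [k*w, (k+1)*w), with a final
    overflow bin for distances > max_distance."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    distances = np.asarray(distances, dtype=float)
    n_bins = int(np.ceil(max_distance / bin_width))
    counts = np.zeros(n_bins + 1, dtype=int)
    idx = np.floor(distances / bin_width).astype(int)
    for d, i in zip(distances, idx):
        counts[min(i, n_bins - 1) if d <= max_distance else n_bins] += 1
    return counts
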