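"""Genome coordinate model: chromosomes, intervals and point features.

All coordinates throughout the package are 0-based, half-open. Converters
from 1-based inclusive tables live at the I/O boundary (:mod:`dedomains.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Genome", "Interval", "FeatureSet", "DomainMap"]


@dataclass(frozen=True)
class Genome:
    """Ordered set of chromosomes with lengths in bp."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in dict(self.chromosomes)

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return -(-self.length(chrom) // bin_width)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Genome":
        return cls(tuple(d.items()))


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with an optional label."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class FeatureSet:
    """Point features (TSSs, binding summits) with optional strand and class label.

    Backed by a DataFrame with columns ``chrom``, ``pos``, ``strand``,
    ``label``. Strand is carried but ignored by all window operations.
    """

    COLUMNS = ["chrom", "pos", "strand", "label"]

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None):
        df = df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = None
        self.df = df[self.COLUMNS].reset_index(drop=True)
        if genome is not None:
            for chrom, sub in self.df.groupby("chrom"):
                length = genome.length(str(chrom))
                bad = sub[(sub["pos"] < 0) | (sub["pos"] >= length)]
                if len(bad):
                    row = bad.iloc[0]
                    raise ValueError(
                        f"feature at {row['chrom']}:{row['pos']} outside chromosome bounds"
                    )

    def __len__(self) -> int:
        return len(self.df)

    def classes(self) -> list[str]:
        labels = self.df["label"].dropna().unique().tolist()
        return sorted(str(x) for x in labels)

    def subset(self, label: str) -> "FeatureSet":
        return FeatureSet(self.df[self.df["label"] == label])

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple], genome: Genome | None = None
    ) -> "FeatureSet":
        """Build from (chrom, pos[, strand[, label]]) tuples."""
        rows = []
        for rec in records:
            chrom, pos = rec[0], rec[1]
            strand = rec[2] if len(rec) > 2 else None
            label = rec[3] if len(rec) > 3 else None
            rows.append((chrom, int(pos), strand, label))
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS), genome)


@dataclass
class DomainMap:
    """Ordered, non-overlapping labelled intervals partitioning chromosomes.

    Labels are ``"D"`` (H3K27me3-depleted), ``"E"`` (enriched) or ``None``
    for unassigned gaps (probe deserts that could not be closed).
    """

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        prev: Interval | None = None
        for iv in self.intervals:
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValueError(f"overlapping intervals {prev} / {iv}")
            prev = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def on(self, chrom: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]

    def domains(self, label: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == label]

    def assign(self, chrom: str, pos: int) -> Interval | None:
        """Unique interval containing ``pos`` (half-open), or None."""
        ivs = self.on(chrom)
        starts = np.array([iv.start for iv in ivs])
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        if idx >= 0 and ivs[idx].contains(pos):
            return ivs[idx]
        return None

    def label_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized domain label per position ('D'/'E'/None); None outside
        any interval. Positions may be float (e.g. scaled coordinates)."""
        if not hasattr(self, "_index_cache"):
            self._index_cache: dict[str, tuple] = {}
        if chrom not in self._index_cache:
            ivs = self.on(chrom)
            self._index_cache[chrom] = (
                np.array([iv.start for iv in ivs], dtype=float),
                np.array([iv.end for iv in ivs], dtype=float),
                np.array([iv.label for iv in ivs], dtype=object),
            )
        starts, ends, labels = self._index_cache[chrom]
        positions = np.asarray(positions, dtype=float)
        out = np.full(positions.shape, None, dtype=object)
        if len(starts) == 0:
            return out
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = labels[idx[ok]]
        return out

    def borders(self, chrom: str, include_ends: bool = False) -> np.ndarray:
        """D/E transition positions on ``chrom`` in bp, sorted and deduplicated.

        A D|gap|E junction contributes a single border at the gap midpoint;
        same-label junctions across a gap contribute none. Chromosome-end
        edges are excluded unless ``include_ends``.
        """
        ivs = self.on(chrom)
        out: list[float] = []
        if include_ends and ivs:
            out.append(ivs[0].start)
            out.append(ivs[-1].end)
        # walk over labelled intervals, tracking gaps between them
        labelled = [iv for iv in ivs if iv.label is not None]
        for a, b in zip(labelled, labelled[1:]):
            if a.label == b.label:
                continue
            if a.end == b.start:
                out.append(a.end)
            else:  # separated by an unassigned gap: midpoint, flagged upstream
                out.append((a.end + b.start) / 2.0)
        return np.unique(np.asarray(sorted(out), dtype=np.float64))

    def merged(self) -> "DomainMap":
        """Merge adjacent same-label intervals per chromosome."""
        out: list[Interval] = []
        for iv in self.intervals:
            if (
                out
                and out[-1].chrom == iv.chrom
                and out[-1].end == iv.start
                and out[-1].label == iv.label
            ):
                out[-1] = Interval(iv.chrom, out[-1].start, iv.end, iv.label)
            else:
                out.append(iv)
        return DomainMap(out)
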