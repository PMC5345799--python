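"""Signal tracks: probe-level (tiling-array) and fixed-width binned tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import Genome, Interval

__all__ = ["ProbeTrack", "BinnedTrack"]


@dataclass
class ProbeTrack:
    """Probe-level log2-ratio track: (chrom, start, end, score) records.

    Records are kept sorted by chromosome then start; overlaps within a
    chromosome are rejected (tiling-array probes do not overlap).
    """

    genome: Genome
    df: pd.DataFrame  # columns chrom, start, end, score

    def __post_init__(self) -> None:
        df = self.df.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in self.genome:
                raise ValueError(f"unknown chromosome {chrom!r}")
            ends = sub["end"].to_numpy()
            starts = sub["start"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping records on {chrom}")
            if starts[0] < 0 or ends[-1] > self.genome.length(str(chrom)):
                raise ValueError(f"record outside chromosome bounds on {chrom}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def scores(self, chrom: str) -> np.ndarray:
        return self.on(chrom)["score"].to_numpy(dtype=float)

    def with_scores(self, chrom_scores: dict[str, np.ndarray]) -> "ProbeTrack":
        """Copy with per-chromosome score vectors replaced (same probe layout)."""
        df = self.df.copy()
        for chrom, vals in chrom_scores.items():
            mask = df["chrom"] == chrom
            if mask.sum() != len(vals):
                raise ValueError(f"score vector length mismatch on {chrom}")
            df.loc[mask, "score"] = np.asarray(vals, dtype=float)
        return ProbeTrack(self.genome, df)


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome bin scores; NaN marks missing bins."""

    genome: Genome
    bin_width: int
    scores: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, vec in self.scores.items():
            expected = self.genome.n_bins(chrom, self.bin_width)
            vec = np.asarray(vec, dtype=float)
            if len(vec) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {len(vec)}"
                )
            present = vec[~np.isnan(vec)]
            if present.size and not np.all(np.isfinite(present)):
                raise ValueError(f"{chrom}: non-finite scores present")
            self.scores[chrom] = vec

    def chromosomes(self) -> list[str]:
        return list(self.scores)

    def missing_runs(self, chrom: str) -> list[Interval]:
        """Maximal runs of missing bins as bp intervals (clipped to chrom end)."""
        vec = self.scores[chrom]
        isnan = np.isnan(vec)
        out: list[Interval] = []
        length = self.genome.length(chrom)
        i = 0
        while i < len(vec):
            if isnan[i]:
                j = i
                while j < len(vec) and isnan[j]:
                    j += 1
                out.append(
                    Interval(chrom, i * self.bin_width, min(j * self.bin_width, length))
                )
                i = j
            else:
                i += 1
        return out
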