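"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: chrom.sizes (Genome), bedGraph (probe and binned tracks), BED
(domain maps, features, interval annotations), tab-delimited valid-pairs
tables, and dense / sparse-triplet contact matrices with a ``#`` metadata
header line carrying chromosome, length and resolution.

All on-disk interval formats are BED-like and 0-based half-open, matching
the in-memory convention; no conversion is needed at this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .genome import FeatureSet, Genome, Interval, DomainMap
from .tracks import BinnedTrack, ProbeTrack

logger = logging.getLogger("dedomains")

__all__ = [
    "ParseError",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_binned_track",
    "write_binned_track",
    "read_pairs",
    "write_pairs",
    "PairRecord",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_domain_map",
    "write_domain_map",
    "read_bed_features",
    "write_bed_features",
    "read_contact_matrix",
    "write_contact_matrix",
    "one_based_to_zero_based",
]


class ParseError(ValueError):
    """Malformed input line; message carries path and line number."""


def one_based_to_zero_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start - 1, end


# -- genome ----------------------------------------------------------------


def read_chrom_sizes(path: str | Path) -> Genome:
    chroms: list[tuple[str, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
        chroms.append((parts[0], int(parts[1])))
    return Genome(tuple(chroms))


def write_chrom_sizes(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


# -- bedGraph tracks -------------------------------------------------------


def read_bedgraph(path: str | Path, genome: Genome) -> ProbeTrack:
    """Read a 4-column bedGraph into a probe-level track.

    Records must lie within the genome and may not overlap; a malformed
    line raises :class:`ParseError` with its line number.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated columns")
        chrom, start_s, end_s, score_s = parts
        try:
            start, end, score = int(start_s), int(end_s), float(score_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if chrom not in genome:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end <= start")
        rows.append((chrom, start, end, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    logger.info("read_bedgraph: %s -> %d records", path, len(df))
    return ProbeTrack(genome, df)


def write_bedgraph(track: ProbeTrack, path: str | Path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.score:.{precision}f}\n")


def read_binned_track(
    path: str | Path, genome: Genome, bin_width: int
) -> BinnedTrack:
    """Read a bin-resolution bedGraph; bins absent from the file are missing."""
    probe = read_bedgraph(path, genome)
    scores: dict[str, np.ndarray] = {}
    for chrom in probe.df["chrom"].unique():
        vec = np.full(genome.n_bins(str(chrom), bin_width), np.nan)
        sub = probe.on(str(chrom))
        idx = sub["start"].to_numpy() // bin_width
        if np.any(sub["start"].to_numpy() % bin_width != 0):
            raise ParseError(f"{path}: record not aligned to {bin_width} bp bins")
        vec[idx] = sub["score"].to_numpy()
        scores[str(chrom)] = vec
    return BinnedTrack(genome, bin_width, scores)


def write_binned_track(
    track: BinnedTrack, path: str | Path, precision: int = 6
) -> None:
    """Write non-missing bins as bedGraph records at bin resolution."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            vec = track.scores[chrom]
            length = track.genome.length(chrom)
            for i in np.flatnonzero(~np.isnan(vec)):
                start = int(i) * track.bin_width
                end = min(start + track.bin_width, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{vec[i]:.{precision}f}\n")


# -- Hi-C valid pairs ------------------------------------------------------


@dataclass(frozen=True)
class PairRecord:
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int

    @property
    def is_trans(self) -> bool:
        return self.chrom1 != self.chrom2


def read_pairs(path: str | Path, genome: Genome) -> Iterator[PairRecord]:
    """Stream a tab-delimited (chrom1, pos1, chrom2, pos2) valid-pairs table.

    Pairs touching an unknown chromosome are skipped (counted, not fatal);
    inter-chromosomal pairs are yielded with ``is_trans`` set and are
    excluded later by the matrix builder.
    """
    n_ok = n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom1, pos1, chrom2, pos2 = parts[0], int(parts[1]), parts[2], int(parts[3])
            if chrom1 not in genome or chrom2 not in genome:
                n_skipped += 1
                continue
            n_ok += 1
            yield PairRecord(chrom1, pos1, chrom2, pos2)
    logger.info("read_pairs: %s -> %d parsed, %d skipped", path, n_ok, n_skipped)


def write_pairs(pairs: Iterable[PairRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.chrom1}\t{p.pos1}\t{p.chrom2}\t{p.pos2}\n")


# -- BED intervals / domain maps / features --------------------------------


def read_bed_intervals(path: str | Path, genome: Genome | None = None) -> list[Interval]:
    out: list[Interval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        label = parts[3] if len(parts) > 3 and parts[3] != "." else None
        if genome is not None and chrom not in genome:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        if end <= start:
            raise ParseError(f"{path}:{lineno}: end <= start")
        out.append(Interval(chrom, start, end, label))
    return out


def write_bed_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            name = iv.label if iv.label is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


GAP_NAME = "gap"


def write_domain_map(dmap: DomainMap, path: str | Path) -> None:
    """Write a domain map as BED with the D/E label (or ``gap``) in the name column."""
    with open(path, "w") as fh:
        for iv in dmap:
            name = iv.label if iv.label is not None else GAP_NAME
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_domain_map(path: str | Path, genome: Genome | None = None) -> DomainMap:
    ivs = read_bed_intervals(path, genome)
    fixed = [
        Interval(iv.chrom, iv.start, iv.end, None if iv.label == GAP_NAME else iv.label)
        for iv in ivs
    ]
    return DomainMap(fixed)


def read_bed_features(path: str | Path, genome: Genome | None = None) -> FeatureSet:
    """Read point features from BED: position = interval start (summit convention).

    Column 4 is the class label, column 6 the strand, when present.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
        chrom, start = parts[0], int(parts[1])
        label = parts[3] if len(parts) > 3 and parts[3] != "." else None
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
        rows.append((chrom, start, strand, label))
    return FeatureSet(
        pd.DataFrame(rows, columns=FeatureSet.COLUMNS), genome
    )


def write_bed_features(features: FeatureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in features.df.itertuples(index=False):
            label = row.label if row.label is not None else "."
            strand = row.strand if row.strand is not None else "."
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{label}\t0\t{strand}\n")


# -- contact matrices ------------------------------------------------------


def write_contact_matrix(matrix, path: str | Path, fmt: str = "triplet") -> None:
    """Write a contact matrix as sparse upper-triangle triplets or dense text.

    The first line is a ``#`` metadata header recording chromosome, length
    and resolution so the matrix is self-describing.
    """
    from .hic import ContactMatrix  # local import to avoid a cycle

    assert isinstance(matrix, ContactMatrix)
    header = (
        f"# chrom={matrix.chrom} length={matrix.chrom_length} "
        f"resolution={matrix.resolution} format={fmt}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        if fmt == "dense":
            for row in matrix.values:
                fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")
        elif fmt == "triplet":
            ii, jj = np.nonzero(np.triu(matrix.values != 0))
            for i, j in zip(ii, jj):
                fh.write(f"{i}\t{j}\t{matrix.values[i, j]:.8g}\n")
        else:
            raise ValueError(f"unknown matrix format {fmt!r}")


def read_contact_matrix(path: str | Path):
    from .hic import ContactMatrix

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ParseError(f"{path}:1: missing metadata header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        chrom = meta["chrom"]
        length = int(meta["length"])
        resolution = int(meta["resolution"])
        fmt = meta.get("format", "triplet")
        n = -(-length // resolution)
        values = np.zeros((n, n), dtype=float)
        if fmt == "dense":
            for i, line in enumerate(fh):
                values[i] = np.fromstring(line, sep=" ")
        else:
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                i_s, j_s, v_s = line.split("\t")
                i, j, v = int(i_s), int(j_s), float(v_s)
                values[i, j] = v
                values[j, i] = v
    return ContactMatrix(chrom, length, resolution, values)
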