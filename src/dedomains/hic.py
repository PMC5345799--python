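"""Hi-C contact matrices: binning of valid pairs and coverage-product normalization.

The normalization implements the binomial coverage-product expected model:
with total intra-chromosomal count N and relative coverage
``r_i = rowsum_i / (2N)``, the expected count is ``2 r_i r_j N`` off the
diagonal and ``r_i^2 N`` on it, and the normalized value is
observed / expected. Only the ratio is computed; no significance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .genome import Genome
from .io import PairRecord

logger = logging.getLogger("dedomains")

__all__ = ["ContactMatrix", "bin_pairs", "normalize_coverage_product"]


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned interaction matrix.

    ``values`` holds raw counts or normalized frequencies; ``valid`` marks
    bins with non-zero coverage (all True for raw count matrices).
    """

    chrom: str
    chrom_length: int
    resolution: int
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = -(-self.chrom_length // self.resolution)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} bins for {self.chrom} at {self.resolution} bp"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("contact matrix must be non-negative")
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (n,):
                raise ValueError("validity mask length mismatch")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def bin_of(self, pos: int) -> int:
        return pos // self.resolution


def bin_pairs(
    pairs: Iterable[PairRecord], genome: Genome, resolution: int, chroms: list[str] | None = None
) -> dict[str, ContactMatrix]:
    """Tally intra-chromosomal pairs into symmetric count matrices.

    Each pair increments bins (floor(pos1/res), floor(pos2/res)) and the
    mirror cell; a same-bin pair increments the diagonal once. Trans pairs
    are counted and discarded.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if chroms is None:
        chroms = genome.names
    mats = {
        c: np.zeros((genome.n_bins(c, resolution),) * 2, dtype=float) for c in chroms
    }
    n_intra = n_trans = 0
    for p in pairs:
        if p.is_trans:
            n_trans += 1
            continue
        if p.chrom1 not in mats:
            continue
        i = p.pos1 // resolution
        j = p.pos2 // resolution
        mats[p.chrom1][i, j] += 1
        if i != j:
            mats[p.chrom1][j, i] += 1
        n_intra += 1
    logger.info("bin_pairs: %d intra retained, %d trans discarded", n_intra, n_trans)
    return {
        c: ContactMatrix(c, genome.length(c), resolution, m) for c, m in mats.items()
    }


def normalize_coverage_product(counts: ContactMatrix) -> ContactMatrix:
    """Observed/expected normalization under the coverage-product model.

    Bins with zero coverage are masked invalid and their rows/columns set
    to zero; the normalized value is observed/expected elsewhere. The
    result is invariant to scaling all counts by a positive constant.
    """
    m = counts.values
    # coverage counts pair ends: a same-bin pair contributes both ends to its bin
    coverage = m.sum(axis=1) + np.diag(m)
    n_total = m[np.triu_indices_from(m)].sum()
    if n_total <= 0:
        raise ValueError("all-zero contact matrix")
    valid = coverage > 0
    r = np.where(valid, coverage / (2.0 * n_total), 0.0)
    expected = 2.0 * np.outer(r, r) * n_total
    np.fill_diagonal(expected, r**2 * n_total)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(expected > 0, m / expected, 0.0)
    normalized[~valid, :] = 0.0
    normalized[:, ~valid] = 0.0
    logger.info(
        "normalize_coverage_product: %s N=%g, %d/%d bins valid",
        counts.chrom, n_total, int(valid.sum()), counts.n_bins,
    )
    return ContactMatrix(
        counts.chrom, counts.chrom_length, counts.resolution, normalized, valid
    )
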