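"""Maximum-likelihood block segmentation of a contact matrix into TADs.

Model: on the log-transformed normalized matrix, cells inside a diagonal
block share a block-specific mean, all off-block cells share a single
global mean, and all cells share one normal variance. With the off-block
mean held fixed, the log-likelihood decomposes additively over segments,
so the optimal boundaries for every candidate boundary count K are found
exactly by dynamic programming over segment endpoints. The off-block mean
is profiled: estimated from far-from-diagonal cells, then re-estimated
once from the off-block cells of the first DP partition and the DP re-run.

Border filtering follows the rule of ranking boundaries by individual
log-likelihood gain, locating the elbow of the sorted gain curve (maximum
distance to the chord joining its first and last points), treating the
boundaries past the elbow as the linear portion, and removing the lowest
fraction (default 10%) of that portion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import Interval
from .hic import ContactMatrix

logger = logging.getLogger("dedomains")

__all__ = [
    "SegmentationResult",
    "segment_matrix",
    "segmentation_cost_matrix",
    "partition_sse",
    "filter_boundaries",
    "boundaries_to_tads",
]

_VAR_FLOOR = 1e-12  # variance floor for noiseless matrices


@dataclass
class SegmentationResult:
    chrom: str
    resolution: int
    n_bins: int
    boundaries: list[int]  # internal boundary bin indices, increasing
    gains: list[float]  # per-boundary log-likelihood gain, same order
    loglik_per_k: list[float]  # total model log-likelihood for K = 0..K_max
    mu0: float  # fixed off-block mean (standardized log scale)
    baseline_sse: float  # SSE with every cell off-block, around mu0
    n_cells: int

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("boundaries must be strictly increasing")


def _transform(matrix: ContactMatrix, transform: str) -> tuple[np.ndarray, np.ndarray]:
    """Log-transform and standardize; returns (y, weight) with invalid bins
    weighted out."""
    x = matrix.values
    if transform == "log1p":
        y = np.log1p(x)
    elif transform == "log":
        with np.errstate(divide="ignore"):
            y = np.where(x > 0, np.log(np.maximum(x, 1e-300)), 0.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    w = np.outer(matrix.valid, matrix.valid).astype(float)
    if transform == "log":
        w = w * (x > 0)
    mean = np.average(y, weights=w) if w.sum() else 0.0
    sd = np.sqrt(np.average((y - mean) ** 2, weights=w)) if w.sum() else 1.0
    if sd <= 0:
        sd = 1.0
    return (y - mean) / sd, w


def _prefix(y: np.ndarray, w: np.ndarray):
    """Prefix structures for O(1) triangle sums over any diagonal block."""
    yw = y * w
    P1 = np.zeros((len(y) + 1,) * 2)
    Pw = np.zeros_like(P1)
    P1[1:, 1:] = np.cumsum(np.cumsum(yw, axis=0), axis=1)
    Pw[1:, 1:] = np.cumsum(np.cumsum(w, axis=0), axis=1)
    d1 = np.concatenate([[0.0], np.cumsum(np.diag(yw))])
    dw = np.concatenate([[0.0], np.cumsum(np.diag(w))])
    return P1, Pw, d1, dw


def _triangle_sums(P1, Pw, d1, dw, i: np.ndarray, j: np.ndarray):
    """Weighted sum and cell count over {(a,b): i<=a<=b<j} for index arrays."""
    sq = P1[j, j] - P1[i, j] - P1[j, i] + P1[i, i]
    sqw = Pw[j, j] - Pw[i, j] - Pw[j, i] + Pw[i, i]
    s1 = (sq + (d1[j] - d1[i])) / 2.0
    nc = (sqw + (dw[j] - dw[i])) / 2.0
    return s1, nc


def segmentation_cost_matrix(
    y: np.ndarray, w: np.ndarray, mu0: float
) -> np.ndarray:
    """Additive segment costs C[i, j] for segment [i, j), given the fixed
    off-block mean.

    C[i, j] = -(s1 - nc*mu0)^2 / nc where s1, nc are the weighted sum and
    count of the segment's diagonal-triangle cells: the change in total SSE
    when those cells switch from the off-block mean to their own block
    mean. Always <= 0, so the optimum improves monotonically with K.
    """
    n = len(y)
    P1, Pw, d1, dw = _prefix(y, w)
    ii, jj = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    s1, nc = _triangle_sums(P1, Pw, d1, dw, ii, jj)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = -((s1 - nc * mu0) ** 2) / nc
    c[~(nc > 0)] = 0.0
    c[ii >= jj] = np.inf  # only i < j defines a segment
    np.fill_diagonal(c, np.inf)
    return c


def partition_sse(
    cost: np.ndarray, baseline: float, boundaries: list[int], n: int
) -> float:
    """Total SSE of the partition with the given internal boundaries."""
    edges = [0, *boundaries, n]
    return baseline + sum(cost[a, b] for a, b in zip(edges, edges[1:]))


def _loglik_from_sse(sse: float, n_cells: int) -> float:
    var = max(sse / n_cells, _VAR_FLOOR)
    return -0.5 * n_cells * (np.log(2.0 * np.pi * var) + 1.0)


def _dp(cost: np.ndarray, k_max: int, n: int):
    """Exact DP over segment endpoints.

    Computes, for each boundary budget K = 0..k_max, the minimum total
    cost over partitions with *at most* K internal boundaries (segment
    costs can be positive-sum trades, so the exact-K optimum is not
    monotone, but the budgeted optimum is). Returns per-budget costs and
    boundary solutions.
    """
    per_exact_cost = [cost[0, n]]
    all_parents = [np.zeros(n + 1, dtype=np.int64)]
    exact_solutions: list[list[int]] = [[]]
    prev = cost[0, : n + 1].copy()  # one segment
    for k in range(2, k_max + 2):  # k segments = k-1 internal boundaries
        m = prev[:, None] + cost
        parent = np.argmin(m, axis=0)
        cur = m[parent, np.arange(n + 1)]
        all_parents.append(parent)
        per_exact_cost.append(cur[n])
        bounds = []
        j = n
        for kk in range(k - 1, 0, -1):
            j = int(all_parents[kk][j])
            bounds.append(j)
        exact_solutions.append(sorted(bounds))
        prev = cur
    per_k_cost: list[float] = []
    solutions: list[list[int]] = []
    best_k = 0
    for k in range(k_max + 1):
        if per_exact_cost[k] < per_exact_cost[best_k]:
            best_k = k
        per_k_cost.append(per_exact_cost[best_k])
        solutions.append(exact_solutions[best_k])
    return per_k_cost, solutions


def _estimate_mu0_initial(y: np.ndarray, w: np.ndarray) -> float:
    """Mean of far-from-diagonal cells (distance >= n//2), which are
    off-block for any block shorter than half the chromosome."""
    n = len(y)
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    far = (dist >= max(n // 2, 1)) & (w > 0)
    if far.any():
        return float(np.average(y[far], weights=w[far]))
    return float(np.average(y, weights=w)) if w.sum() else 0.0


def _mu0_from_partition(y, w, boundaries: list[int]) -> float | None:
    n = len(y)
    within = np.zeros((n, n), dtype=bool)
    edges = [0, *boundaries, n]
    for a, b in zip(edges, edges[1:]):
        within[a:b, a:b] = True
    off = ~within & (w > 0)
    off &= np.triu(np.ones((n, n), dtype=bool))
    if not off.any():
        return None
    return float(np.average(y[off], weights=w[off]))


def _forward_selection_gains(
    cost: np.ndarray, baseline: float, bset: list[int], n: int, n_cells: int
) -> dict[int, float]:
    """Marginal log-likelihood gain of each boundary along the forward
    selection path restricted to the final boundary set."""
    gains: dict[int, float] = {}
    selected: list[int] = []
    remaining = list(bset)
    ll_cur = _loglik_from_sse(partition_sse(cost, baseline, [], n), n_cells)
    while remaining:
        best_b, best_ll = None, -np.inf
        for b in remaining:
            trial = sorted(selected + [b])
            ll = _loglik_from_sse(partition_sse(cost, baseline, trial, n), n_cells)
            if ll > best_ll:
                best_b, best_ll = b, ll
        gains[best_b] = best_ll - ll_cur  # type: ignore[index]
        selected.append(best_b)  # type: ignore[arg-type]
        selected.sort()
        remaining.remove(best_b)
        ll_cur = best_ll
    return gains


def segment_matrix(
    matrix: ContactMatrix,
    max_boundaries: int | None = None,
    transform: str = "log1p",
    refine_mu0: bool = True,
) -> SegmentationResult:
    """Exact DP block segmentation with at most ``max_boundaries`` boundaries.

    For every boundary budget K = 0..max_boundaries the DP finds the
    partition maximizing the model log-likelihood over all placements with
    at most K internal boundaries, so ``loglik_per_k`` is non-decreasing.
    Returns the boundary set at the full budget (default: bins//15, a mean
    segment of >= 150 kb at 10-kb bins) with per-boundary gains; pass the
    result to :func:`filter_boundaries` to apply the border filter.
    """
    n = matrix.n_bins
    if n < 3:
        raise ValueError("matrix must have at least 3 bins")
    if max_boundaries is None:
        max_boundaries = max(n // 15, 1)
    if max_boundaries < 1:
        raise ValueError("max_boundaries must be >= 1")
    max_boundaries = min(max_boundaries, n - 1)
    y, w = _transform(matrix, transform)
    mu0 = _estimate_mu0_initial(y, w)

    def _run(mu: float):
        c = segmentation_cost_matrix(y, w, mu)
        base = float(np.sum(w * (y - mu) ** 2 * _upper_weight(n)))
        costs, sols = _dp(c, max_boundaries, n)
        return c, base, costs, sols

    cost, baseline, per_k_cost, solutions = _run(mu0)
    if refine_mu0:
        new_mu0 = _mu0_from_partition(y, w, solutions[max_boundaries])
        if new_mu0 is not None and abs(new_mu0 - mu0) > 1e-12:
            mu0 = new_mu0
            cost, baseline, per_k_cost, solutions = _run(mu0)
    n_cells = int(round(float(np.sum(w * _upper_weight(n)))))
    logliks = [_loglik_from_sse(baseline + c, n_cells) for c in per_k_cost]
    boundaries = solutions[max_boundaries]
    gain_map = _forward_selection_gains(cost, baseline, boundaries, n, n_cells)
    gains = [gain_map[b] for b in boundaries]
    logger.info(
        "segment_matrix: %s n=%d K=%d mu0=%.4f LL range [%.1f, %.1f]",
        matrix.chrom, n, max_boundaries, mu0, logliks[0], logliks[-1],
    )
    return SegmentationResult(
        matrix.chrom, matrix.resolution, n, boundaries, gains,
        logliks, mu0, baseline, n_cells,
    )


def _upper_weight(n: int) -> np.ndarray:
    """1 on the upper triangle incl. diagonal, 0 below (cells counted once)."""
    return np.triu(np.ones((n, n)))


def filter_boundaries(
    result: SegmentationResult, drop_fraction: float = 0.10
) -> list[int]:
    """Drop the weakest borders: rank by gain, find the elbow of the sorted
    gain curve, and remove the lowest ``drop_fraction`` of the linear
    portion past the elbow. Ties in gain are broken by genomic position
    with the leftmost kept. Fewer than 3 boundaries are returned as-is."""
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    bounds = np.asarray(result.boundaries)
    gains = np.asarray(result.gains, dtype=float)
    if len(bounds) < 3:
        if len(bounds):
            logger.warning("fewer than 3 boundaries; border filter skipped")
        return sorted(int(b) for b in bounds)
    order = np.lexsort((bounds, -gains))  # gain desc, position asc on ties
    g = gains[order]
    m = len(g)
    # chord from (0, g[0]) to (m-1, g[-1]); elbow = max perpendicular distance
    xs = np.arange(m, dtype=float)
    dx, dy = m - 1.0, g[-1] - g[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * xs - dx * (g - g[0])) / (norm if norm > 0 else 1.0)
    elbow = int(np.argmax(dist))
    linear = order[elbow:]
    n_drop = int(np.floor(drop_fraction * len(linear)))
    drop_idx = {int(j) for j in linear[len(linear) - n_drop :]} if n_drop else set()
    return sorted(int(b) for i, b in enumerate(bounds) if i not in drop_idx)


def boundaries_to_tads(
    boundaries: list[int], chrom: str, chrom_length: int, resolution: int
) -> list[Interval]:
    """Consecutive boundaries plus the chromosome ends define TAD intervals."""
    edges_bp = [0] + [b * resolution for b in boundaries] + [chrom_length]
    return [
        Interval(chrom, a, b, "TAD") for a, b in zip(edges_bp, edges_bp[1:])
    ]
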