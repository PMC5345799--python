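"""Two-state Gaussian HMM segmentation of a binned H3K27me3 track.

Per chromosome, a two-state hidden Markov model with normal emissions is
fitted by expectation-maximization to the 1-kb binned signal, the
most-probable state path is decoded, the low-mean state is labelled D
(depleted) and the high-mean state E (enriched), runs of equal labels are
combined into regions, and probe gaps flanked by the same state are closed.

Missing bins (probe deserts) contribute no emission term — their emission
probability is 1 for both states — so transition information still
propagates through gaps before the explicit region-level gap-closing pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .genome import DomainMap, Interval
from .tracks import BinnedTrack

logger = logging.getLogger("dedomains")

__all__ = [
    "HmmParams",
    "HmmFit",
    "fit_two_state_hmm",
    "decode_states",
    "label_states",
    "bins_to_regions",
    "close_probe_gaps",
    "segment_track",
]

SD_FLOOR = 1e-3  # emission SDs are clamped here to avoid degenerate spikes
MISSING_STATE = -1


@dataclass(frozen=True)
class HmmParams:
    """Emission and transition parameters of the two-state model."""

    means: tuple[float, float]
    sds: tuple[float, float]
    transitions: tuple[tuple[float, float], tuple[float, float]]
    initial: tuple[float, float]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sds):
            raise ValueError("emission SDs must be positive")
        for row in self.transitions:
            if abs(sum(row) - 1.0) > 1e-9:
                raise ValueError("transition rows must sum to 1")
        if abs(sum(self.initial) - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")

    @property
    def stay_probabilities(self) -> tuple[float, float]:
        return self.transitions[0][0], self.transitions[1][1]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.array(self.means),
            np.array(self.sds),
            np.array(self.transitions),
            np.array(self.initial),
        )


@dataclass
class HmmFit:
    """Fit result: parameters plus the EM trajectory and convergence status."""

    params: HmmParams
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


@njit(cache=False)
def _forward_backward(B, A, pi):  # pragma: no cover - exercised via fit
    """Scaled forward-backward. B holds per-bin emission likelihoods
    (relative; missing bins carry 1 for both states). Returns posterior
    gamma, summed transition posteriors xi, and sum(log scale)."""
    n = B.shape[0]
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    a0 = pi[0] * B[0, 0]
    a1 = pi[1] * B[0, 1]
    s = a0 + a1
    alpha[0, 0] = a0 / s
    alpha[0, 1] = a1 / s
    scale[0] = s
    for t in range(1, n):
        a0 = (alpha[t - 1, 0] * A[0, 0] + alpha[t - 1, 1] * A[1, 0]) * B[t, 0]
        a1 = (alpha[t - 1, 0] * A[0, 1] + alpha[t - 1, 1] * A[1, 1]) * B[t, 1]
        s = a0 + a1
        alpha[t, 0] = a0 / s
        alpha[t, 1] = a1 / s
        scale[t] = s
    beta0 = 1.0
    beta1 = 1.0
    gamma = np.empty((n, 2))
    xi = np.zeros((2, 2))
    g0 = alpha[n - 1, 0]
    g1 = alpha[n - 1, 1]
    gamma[n - 1, 0] = g0
    gamma[n - 1, 1] = g1
    for t in range(n - 2, -1, -1):
        bb0 = B[t + 1, 0] * beta0
        bb1 = B[t + 1, 1] * beta1
        x00 = alpha[t, 0] * A[0, 0] * bb0
        x01 = alpha[t, 0] * A[0, 1] * bb1
        x10 = alpha[t, 1] * A[1, 0] * bb0
        x11 = alpha[t, 1] * A[1, 1] * bb1
        tot = x00 + x01 + x10 + x11
        xi[0, 0] += x00 / tot
        xi[0, 1] += x01 / tot
        xi[1, 0] += x10 / tot
        xi[1, 1] += x11 / tot
        nb0 = (A[0, 0] * bb0 + A[0, 1] * bb1) / scale[t + 1]
        nb1 = (A[1, 0] * bb0 + A[1, 1] * bb1) / scale[t + 1]
        beta0, beta1 = nb0, nb1
        g0 = alpha[t, 0] * beta0
        g1 = alpha[t, 1] * beta1
        gs = g0 + g1
        gamma[t, 0] = g0 / gs
        gamma[t, 1] = g1 / gs
    loglik = 0.0
    for t in range(n):
        loglik += np.log(scale[t])
    return gamma, xi, loglik


@njit(cache=False)
def _viterbi(logB, logA, logpi):  # pragma: no cover - exercised via decode
    n = logB.shape[0]
    back = np.empty((n, 2), dtype=np.int8)
    v0 = logpi[0] + logB[0, 0]
    v1 = logpi[1] + logB[0, 1]
    for t in range(1, n):
        c00 = v0 + logA[0, 0]
        c10 = v1 + logA[1, 0]
        if c00 >= c10:
            nv0 = c00 + logB[t, 0]
            back[t, 0] = 0
        else:
            nv0 = c10 + logB[t, 0]
            back[t, 0] = 1
        c01 = v0 + logA[0, 1]
        c11 = v1 + logA[1, 1]
        if c01 >= c11:
            nv1 = c01 + logB[t, 1]
            back[t, 1] = 0
        else:
            nv1 = c11 + logB[t, 1]
            back[t, 1] = 1
        v0, v1 = nv0, nv1
    path = np.empty(n, dtype=np.int8)
    path[n - 1] = 0 if v0 >= v1 else 1
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _emission_loglik(x: np.ndarray, observed: np.ndarray, means, sds) -> np.ndarray:
    """Per-bin per-state emission log-likelihood; 0 (prob 1) at missing bins."""
    n = len(x)
    logB = np.zeros((n, 2))
    xo = x[observed]
    for k in range(2):
        logB[observed, k] = (
            -0.5 * np.log(2.0 * np.pi)
            - np.log(sds[k])
            - 0.5 * ((xo - means[k]) / sds[k]) ** 2
        )
    return logB


def _initial_params(x_obs: np.ndarray, rng: np.random.Generator | None) -> HmmParams:
    """Deterministic two-cluster initialization: split at the track median,
    empirical mean/SD per half, stay-probability 0.95. When ``rng`` is
    given, the means are perturbed for a random restart."""
    med = np.median(x_obs)
    lower = x_obs[x_obs <= med]
    upper = x_obs[x_obs > med]
    if upper.size == 0:  # constant track; nudge apart
        lower, upper = x_obs, x_obs + np.std(x_obs) + 1.0
    m = [float(np.mean(lower)), float(np.mean(upper))]
    s = [max(float(np.std(lower)), SD_FLOOR), max(float(np.std(upper)), SD_FLOOR)]
    if rng is not None:
        spread = max(m[1] - m[0], 1e-3)
        m = [m[0] + rng.normal(0, 0.25 * spread), m[1] + rng.normal(0, 0.25 * spread)]
    return HmmParams(
        (m[0], m[1]), (s[0], s[1]), ((0.95, 0.05), (0.05, 0.95)), (0.5, 0.5)
    )


def _em(
    x: np.ndarray,
    observed: np.ndarray,
    start: HmmParams,
    tol: float,
    max_iter: int,
) -> HmmFit:
    means, sds, A, pi = (np.array(v, dtype=float) for v in start.as_arrays())
    logliks: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logB = _emission_loglik(x, observed, means, sds)
        rowmax = logB.max(axis=1)
        B = np.exp(logB - rowmax[:, None])
        gamma, xi, ll_rel = _forward_backward(B, A, pi)
        ll = float(ll_rel + rowmax.sum())
        logliks.append(ll)
        # M step
        g_obs = gamma[observed]
        xo = x[observed]
        w = g_obs.sum(axis=0)
        means = (g_obs * xo[:, None]).sum(axis=0) / w
        var = (g_obs * (xo[:, None] - means[None, :]) ** 2).sum(axis=0) / w
        sds = np.sqrt(var)
        if np.any(sds < SD_FLOOR):
            logger.warning("emission SD collapsed below floor; clamped to %g", SD_FLOOR)
            sds = np.maximum(sds, SD_FLOOR)
        A = xi / xi.sum(axis=1, keepdims=True)
        pi = gamma[0] / gamma[0].sum()
        if len(logliks) > 1:
            delta = logliks[-1] - logliks[-2]
            if delta < -1e-6 * (1.0 + abs(logliks[-2])):
                logger.warning("EM log-likelihood decreased by %g", -delta)
            if abs(delta) < tol * (1.0 + abs(logliks[-2])):
                converged = True
                break
    params = HmmParams(
        (float(means[0]), float(means[1])),
        (float(sds[0]), float(sds[1])),
        (
            (float(A[0, 0]), float(A[0, 1])),
            (float(A[1, 0]), float(A[1, 1])),
        ),
        (float(pi[0]), float(pi[1])),
    )
    return HmmFit(params, logliks, converged, it)


def fit_two_state_hmm(
    track: BinnedTrack,
    chrom: str,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 1,
) -> HmmFit:
    """Fit the two-state normal-emission HMM to one chromosome by EM.

    The default single start uses the deterministic median-split
    initialization; ``n_starts > 1`` adds seeded random restarts and keeps
    the best likelihood. Requires at least 100 non-missing bins.
    """
    x = track.scores[chrom]
    observed = ~np.isnan(x)
    if not observed.any():
        raise ValueError(f"{chrom}: all bins missing")
    if observed.sum() < 100:
        raise ValueError(f"{chrom}: fewer than 100 non-missing bins")
    x = np.where(observed, x, 0.0)
    fits = [_em(x, observed, _initial_params(x[observed], None), tol, max_iter)]
    rng = np.random.default_rng(seed)
    for _ in range(n_starts - 1):
        start = _initial_params(x[observed], rng)
        fits.append(_em(x, observed, start, tol, max_iter))
    best = max(fits, key=lambda f: f.log_likelihoods[-1])
    logger.info(
        "fit_two_state_hmm: %s means=%s sds=%s stay=%s iter=%d converged=%s",
        chrom, best.params.means, best.params.sds,
        best.params.stay_probabilities, best.n_iter, best.converged,
    )
    return best


def decode_states(
    track: BinnedTrack, chrom: str, params: HmmParams, method: str = "viterbi"
) -> np.ndarray:
    """Per-bin state indices; missing bins get -1.

    ``viterbi`` (default) returns the joint most-probable path;
    ``posterior`` maximizes the per-bin posterior.
    """
    x = track.scores[chrom]
    observed = ~np.isnan(x)
    xx = np.where(observed, x, 0.0)
    means, sds, A, pi = params.as_arrays()
    logB = _emission_loglik(xx, observed, means, sds)
    if method == "viterbi":
        with np.errstate(divide="ignore"):
            path = _viterbi(logB, np.log(A), np.log(pi))
        states = np.asarray(path, dtype=np.int8)
    elif method == "posterior":
        rowmax = logB.max(axis=1)
        B = np.exp(logB - rowmax[:, None])
        gamma, _, _ = _forward_backward(B, A, pi)
        states = np.argmax(gamma, axis=1).astype(np.int8)
    else:
        raise ValueError(f"unknown decoding method {method!r}")
    states[~observed] = MISSING_STATE
    return states


def label_states(params: HmmParams) -> dict[int, str]:
    """Map state indices to domain labels: lower emission mean -> D."""
    if params.means[0] == params.means[1]:
        raise ValueError("emission means are equal; D/E labelling undefined")
    low = int(np.argmin(params.means))
    return {low: "D", 1 - low: "E"}


def bins_to_regions(
    states: np.ndarray,
    bin_width: int,
    chrom: str,
    chrom_length: int,
    labels: dict[int, str] | None = None,
) -> DomainMap:
    """Run-length encode per-bin states into labelled regions.

    Missing bins (-1) become unassigned gap intervals. Interval ends are
    clipped to the chromosome length.
    """
    if labels is None:
        labels = {0: "D", 1: "E"}
    out: list[Interval] = []
    n = len(states)
    i = 0
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        label = None if states[i] == MISSING_STATE else labels[int(states[i])]
        start = i * bin_width
        end = min(j * bin_width, chrom_length)
        out.append(Interval(chrom, start, end, label))
        i = j
    return DomainMap(out)


def close_probe_gaps(dmap: DomainMap) -> DomainMap:
    """Absorb unassigned gaps whose two neighbours carry the same label.

    A gap flanked by D on both sides becomes part of one merged D region
    (likewise for E); gaps flanked by different labels, or touching a
    chromosome end, stay unassigned. Idempotent.
    """
    out: list[Interval] = []
    for chrom in dmap.chromosomes():
        ivs = dmap.on(chrom)
        merged: list[Interval] = []
        k = 0
        while k < len(ivs):
            iv = ivs[k]
            if (
                iv.label is None
                and merged
                and merged[-1].label is not None
                and merged[-1].end == iv.start
                and k + 1 < len(ivs)
                and ivs[k + 1].label == merged[-1].label
                and ivs[k + 1].start == iv.end
            ):
                merged[-1] = Interval(
                    chrom, merged[-1].start, ivs[k + 1].end, merged[-1].label
                )
                k += 2
                continue
            if (
                merged
                and merged[-1].label == iv.label
                and merged[-1].label is not None
                and merged[-1].end == iv.start
            ):
                merged[-1] = Interval(chrom, merged[-1].start, iv.end, iv.label)
            else:
                merged.append(iv)
            k += 1
        out.extend(merged)
    return DomainMap(out)


def segment_track(
    track: BinnedTrack,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 1,
    method: str = "viterbi",
) -> tuple[DomainMap, dict[str, HmmFit]]:
    """Fit, decode, label and region-build every chromosome of a track.

    Returns the gap-closed D/E domain map and the per-chromosome fits.
    """
    intervals: list[Interval] = []
    fits: dict[str, HmmFit] = {}
    for chrom in track.chromosomes():
        fit = fit_two_state_hmm(track, chrom, seed=seed, tol=tol,
                                max_iter=max_iter, n_starts=n_starts)
        fits[chrom] = fit
        states = decode_states(track, chrom, fit.params, method=method)
        labels = label_states(fit.params)
        regions = bins_to_regions(
            states, track.bin_width, chrom, track.genome.length(chrom), labels
        )
        intervals.extend(regions.intervals)
    return close_probe_gaps(DomainMap(intervals)), fits
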