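"""Synthetic-data generators with known ground truth.

The generators mirror the statistical structure the analysis assumes: a
two-state Markov chain with Gaussian emissions per 1-kb bin for the ChIP
track; symmetric contact matrices with power-law distance decay, elevated
blocks on E domains, planted D-D corner hotspots and multiplicative
bin-coverage bias; point features preferentially placed in D domains; and
band-like interval sets whose borders are E-domain borders plus normal
jitter.

Every generator is a pure function of (config, seed); independent RNG
streams are derived per generator so that, e.g., adding features does not
perturb the contact matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import DomainMap, FeatureSet, Genome, Interval
from .hic import ContactMatrix
from .hmm import bins_to_regions
from .tracks import BinnedTrack

__all__ = [
    "SimulationConfig",
    "simulate_chip_track",
    "simulate_contact_matrix",
    "simulate_features",
    "simulate_band_set",
]

# stream identifiers keeping the per-generator RNGs independent
_STREAM_CHIP = 1
_STREAM_CONTACT = 2
_STREAM_FEATURES = 3
_STREAM_BANDS = 4


@dataclass
class SimulationConfig:
    """Ground-truth parameters for all generators.

    Emission defaults give a D/E size distribution with median domain
    lengths in the tens-of-kb range at 1-kb bins (stay probability 0.98
    corresponds to a 50-bin mean run length).
    """

    genome: Genome
    bin_width: int = 1000  # ChIP bin width, bp
    hic_resolution: int = 10_000  # contact matrix resolution, bp
    # two-state HMM truth; state 0 = D (depleted), state 1 = E (enriched)
    emission_means: tuple[float, float] = (-0.3, 0.6)
    emission_sds: tuple[float, float] = (0.25, 0.35)
    transitions: tuple[tuple[float, float], tuple[float, float]] = (
        (0.98, 0.02),
        (0.02, 0.98),
    )
    initial: tuple[float, float] = (0.5, 0.5)
    # probe-gap masking: per-bin probability of starting a gap, geometric
    # mean gap length in bins (0 rate disables masking)
    gap_rate: float = 0.0
    gap_mean_bins: float = 5.0
    # contact model
    decay_exponent: float = 1.0
    background: float = 100.0
    e_block_factor: float = 3.0
    hotspot_factor: float = 2.0
    hotspot_prob: float = 0.35
    hotspot_max_flank_bins: int = 10
    coverage_bias_sd: float = 0.1  # lognormal sigma of per-bin bias; 0 = off
    # feature model: class -> (count, probability of placement in D)
    feature_classes: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"tss": (4000, 0.62), "housekeeping": (1200, 0.95)}
    )
    # band model: borders jittered around E-domain borders
    band_jitter_sd: float = 9000.0
    band_min_length: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.emission_sds):
            raise ValueError("emission SDs must be positive")
        for row in self.transitions:
            if abs(sum(row) - 1.0) > 1e-9 or any(p < 0 for p in row):
                raise ValueError("transition rows must be probabilities summing to 1")
        if self.e_block_factor < 1 or self.hotspot_factor < 1:
            raise ValueError("enrichment factors must be >= 1")
        for p in (self.hotspot_prob, self.gap_rate, *self.initial):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _sample_states(rng, n: int, transitions, initial) -> np.ndarray:
    A = np.asarray(transitions)
    u = rng.random(n)
    states = np.empty(n, dtype=np.int8)
    states[0] = int(u[0] >= initial[0])
    for t in range(1, n):
        stay = A[states[t - 1], states[t - 1]]
        if u[t] < stay:
            states[t] = states[t - 1]
        else:
            states[t] = 1 - states[t - 1]
    return states


def simulate_chip_track(cfg: SimulationConfig) -> tuple[BinnedTrack, DomainMap]:
    """Draw per-bin hidden states from the Markov chain and scores from the
    state's normal emission; returns the track and the true domain map.

    When ``gap_rate`` > 0, runs of bins are masked missing (probe deserts);
    the truth map is built from the full state sequence, before masking.
    """
    if not cfg.genome.chromosomes:
        raise ValueError("empty genome")
    rng = cfg.rng(_STREAM_CHIP)
    scores: dict[str, np.ndarray] = {}
    intervals: list[Interval] = []
    for chrom, length in cfg.genome.chromosomes:
        n = cfg.genome.n_bins(chrom, cfg.bin_width)
        states = _sample_states(rng, n, cfg.transitions, cfg.initial)
        means = np.asarray(cfg.emission_means)[states]
        sds = np.asarray(cfg.emission_sds)[states]
        vec = rng.normal(means, sds)
        if cfg.gap_rate > 0:
            starts = np.flatnonzero(rng.random(n) < cfg.gap_rate)
            lengths = rng.geometric(1.0 / cfg.gap_mean_bins, size=len(starts))
            for s, l in zip(starts, lengths):
                vec[s : s + l] = np.nan
        scores[chrom] = vec
        truth = bins_to_regions(states, cfg.bin_width, chrom, length)
        intervals.extend(truth.intervals)
    return BinnedTrack(cfg.genome, cfg.bin_width, scores), DomainMap(intervals)


def _bin_labels(domains: DomainMap, chrom: str, n: int, resolution: int) -> np.ndarray:
    """Domain index per matrix bin (bin midpoint rule); -1 where unassigned."""
    ivs = domains.on(chrom)
    if not ivs:
        raise ValueError(f"domain map empty on {chrom}")
    out = np.full(n, -1, dtype=np.int64)
    mids = np.arange(n) * resolution + resolution // 2
    starts = np.array([iv.start for iv in ivs])
    idx = np.searchsorted(starts, mids, side="right") - 1
    for b in range(n):
        k = idx[b]
        if 0 <= k < len(ivs) and ivs[k].contains(int(mids[b])):
            out[b] = k
    return out


def eligible_e_domains(domains: DomainMap, chrom: str) -> list[tuple[int, Interval]]:
    """E domains strictly flanked by D on both sides, with their index."""
    ivs = domains.on(chrom)
    out = []
    for k, iv in enumerate(ivs):
        if iv.label != "E" or k == 0 or k == len(ivs) - 1:
            continue
        left, right = ivs[k - 1], ivs[k + 1]
        if (
            left.label == "D"
            and right.label == "D"
            and left.end == iv.start
            and right.start == iv.end
        ):
            out.append((k, iv))
    return out


def simulate_contact_matrix(
    cfg: SimulationConfig,
    domains: DomainMap,
    chrom: str,
    resolution: int | None = None,
    with_truth: bool = False,
):
    """Poisson contact matrix with decay, E blocks, corner hotspots and bias.

    Expected count at (i, j) = background x (1+|i-j|)^(-decay)
    x E-block factor when i and j lie in the same E domain
    x hotspot factor when (i, j) couples the two D flanks of a
    planted-hotspot E domain x per-bin coverage bias b_i b_j. Counts are
    Poisson around the expectation, sampled on the upper triangle and
    mirrored, so the matrix is exactly symmetric.

    With ``with_truth`` the planted-hotspot flags per eligible E domain
    are returned alongside the matrix.
    """
    if resolution is None:
        resolution = cfg.hic_resolution
    rng = cfg.rng(_STREAM_CONTACT)
    length = cfg.genome.length(chrom)
    n = cfg.genome.n_bins(chrom, resolution)
    dom_idx = _bin_labels(domains, chrom, n, resolution)
    ivs = domains.on(chrom)
    is_e = np.array([k >= 0 and ivs[k].label == "E" for k in dom_idx])

    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    expected = cfg.background * (1.0 + dist) ** (-cfg.decay_exponent)
    same_e = (
        (dom_idx[:, None] == dom_idx[None, :]) & is_e[:, None] & is_e[None, :]
    )
    expected[same_e] *= cfg.e_block_factor

    planted: dict[tuple[int, int], bool] = {}
    for k, iv in eligible_e_domains(domains, chrom):
        is_planted = bool(rng.random() < cfg.hotspot_prob)
        planted[(iv.start, iv.end)] = is_planted
        if not is_planted:
            continue
        left, right = ivs[k - 1], ivs[k + 1]
        lf0 = max(left.start // resolution, iv.start // resolution - cfg.hotspot_max_flank_bins)
        lf1 = iv.start // resolution
        rf0 = iv.end // resolution
        rf1 = min(-(-right.end // resolution), rf0 + cfg.hotspot_max_flank_bins)
        if lf1 > lf0 and rf1 > rf0:
            expected[lf0:lf1, rf0:rf1] *= cfg.hotspot_factor
            expected[rf0:rf1, lf0:lf1] *= cfg.hotspot_factor

    if cfg.coverage_bias_sd > 0:
        bias = rng.lognormal(0.0, cfg.coverage_bias_sd, size=n)
        expected *= np.outer(bias, bias)

    upper = np.triu(rng.poisson(expected).astype(float))
    counts = upper + np.triu(upper, 1).T
    matrix = ContactMatrix(chrom, length, resolution, counts)
    if with_truth:
        return matrix, planted
    return matrix


def simulate_features(cfg: SimulationConfig, domains: DomainMap) -> FeatureSet:
    """Place point features class by class: inside a D domain with the
    class's D-placement probability, else inside an E domain; uniform
    within the chosen compartment (domains weighted by length)."""
    rng = cfg.rng(_STREAM_FEATURES)
    d_doms = domains.domains("D")
    e_doms = domains.domains("E")
    rows = []
    for label, (count, d_prob) in cfg.feature_classes.items():
        if not d_doms and d_prob > 0:
            raise ValueError("no D domains to place features in")
        if not e_doms and d_prob < 1:
            raise ValueError("no E domains to place features in")
        in_d = rng.random(count) < d_prob
        for use_d, n_feat in ((True, int(in_d.sum())), (False, int((~in_d).sum()))):
            doms = d_doms if use_d else e_doms
            if n_feat == 0:
                continue
            lengths = np.array([len(iv) for iv in doms], dtype=float)
            choice = rng.choice(len(doms), size=n_feat, p=lengths / lengths.sum())
            offsets = rng.random(n_feat)
            for c, u in zip(choice, offsets):
                iv = doms[c]
                pos = iv.start + int(u * len(iv))
                rows.append((iv.chrom, pos, None, label))
    df = pd.DataFrame(rows, columns=FeatureSet.COLUMNS)
    return FeatureSet(df, cfg.genome)


def simulate_band_set(
    cfg: SimulationConfig,
    domains: DomainMap,
    jitter_sd: float | None = None,
    min_length: int | None = None,
) -> list[Interval]:
    """One band per selected E domain, borders = E borders + normal jitter.

    E domains shorter than ``min_length`` are skipped. Jittered borders are
    clipped to the chromosome and a band is forced to at least 1 bp.
    """
    if jitter_sd is None:
        jitter_sd = cfg.band_jitter_sd
    if min_length is None:
        min_length = cfg.band_min_length
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = cfg.rng(_STREAM_BANDS)
    out: list[Interval] = []
    for iv in domains.domains("E"):
        if len(iv) < min_length:
            continue
        length = cfg.genome.length(iv.chrom)
        start = iv.start + (rng.normal(0, jitter_sd) if jitter_sd > 0 else 0.0)
        end = iv.end + (rng.normal(0, jitter_sd) if jitter_sd > 0 else 0.0)
        start = int(np.clip(round(start), 0, length - 1))
        end = int(np.clip(round(end), start + 1, length))
        out.append(Interval(iv.chrom, start, end, "band"))
    return out
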