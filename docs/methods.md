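# Methods

This note documents the models implemented in `dedomains`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical decisions taken where the problem was
genuinely open.

## Coordinate model

All intervals are 0-based, half-open, everywhere: in memory, in BED and
bedGraph I/O, and in every statistic. Converters from 1-based inclusive
tables (`one_based_to_zero_based`) exist only at the I/O boundary. A
feature at a domain's start coordinate belongs to that domain; a feature
at its end coordinate belongs to the next. Strand is carried on features
but ignored by all window operations, which are symmetric.

## ChIP preprocessing

Tiling-array channels are median-scaled to 500, quantile-normalized
(reference distribution = mean of order statistics across channels, ties
resolved by fractional-rank interpolation), averaged across replicates,
and then smoothed to fixed-width bins by the mean probe score per bin.
Binning uses the probe-interval **midpoint** to assign probes to bins —
the symmetric, standard convention for tiling arrays. Bins containing no
probe are *missing* (NaN), never zero; missing bins carry no evidence
and are handled explicitly downstream. Replicate averaging precedes
binning so that smoothing acts on the averaged signal.

TSS scores are the median of probe (default) or bin values overlapping
a ±500 bp window. The developmental position statistic for a gene class
is (mean_class − mean_housekeeping) / (mean_Polycomb − mean_housekeeping),
i.e. class means expressed on a 0–1 scale anchored at the housekeeping
and Polycomb-target means.

## Two-state HMM segmentation

Per chromosome, the binned signal is modelled as a 2-state homogeneous
Markov chain with Gaussian emissions. Parameters (two means, two SDs,
2×2 transition matrix, initial distribution) are estimated by EM over
the non-missing bins.

* **Missing bins** contribute an emission factor of 1 to both states, so
  the chain's transition structure still propagates through probe gaps;
  decoded output assigns them no state. After region building, a gap
  whose two neighbours carry the same label is absorbed into one region;
  a gap between different labels, or at a chromosome end, stays
  unassigned. Border statistics treat a D|gap|E junction as a single
  border at the gap midpoint (flagged as such in output), the unbiased
  choice when the transition point inside the gap is unobserved.
* **Initialization** is deterministic: split the observed scores at the
  median, use each half's empirical mean/SD, stay probability 0.95,
  uniform initial distribution. An optional multi-start mode adds seeded
  random perturbations of the means and keeps the best likelihood. For
  the well-separated bimodal signals this model targets, the
  single deterministic start converges to the same optimum as
  multi-start in practice (and is cross-checked against an independent
  EM implementation in the test suite).
* **Convergence**: relative log-likelihood change below 1e-6 or 500
  iterations; the EM trajectory and convergence flag are returned.
  Emission SDs are floored at 1e-3 to prevent degenerate spikes.
* **Decoding** defaults to the joint most-probable path (Viterbi);
  per-bin posterior maximization is available behind a flag. The state
  with the lower emission mean is labelled D.
* Fitting is **per chromosome**; chromosomes can differ in both signal
  level and domain scale.

The forward-backward and Viterbi kernels are numba-compiled; a 50,000-bin
chromosome fits in a few seconds.

## Hi-C normalization

Valid intra-chromosomal pairs are binned at 10 kb (5 kb for the
short/long-range analysis); trans pairs are counted and discarded, since
every downstream statistic is intra-chromosomal. With N the total
intra-chromosomal pair count and coverage of bin i counting pair *ends*
(a same-bin pair contributes both ends), the relative coverage is
rᵢ = coverageᵢ / 2N, and the expected count is

* expectedᵢⱼ = 2 rᵢ rⱼ N (i ≠ j), expectedᵢᵢ = rᵢ² N.

The normalized value is observed/expected. Σrᵢ = 1 and the result is
invariant to scaling all counts, both verified as test identities. Bins
with zero coverage are masked invalid and stay masked downstream. No
significance test is attached to individual contacts, and no ICE/KR
balancing is performed — the downstream statistics consume the
observed/expected ratio only.

A consequence worth knowing: coverage-product normalization leaves
*composition-dependent* level differences. Bins inside
interaction-dense blocks have inflated coverage, so their normalized
values are depressed relative to sparse-coverage bins at the same
distance. The hotspot detector (below) is designed around this.

## TAD segmentation

The normalized matrix is log-transformed (log(1+x), a pure log option
exists) and standardized. Cells in the upper triangle are modelled as
normal with a block-specific mean when both bins fall in the same
segment, a single shared off-block mean μ₀ otherwise, and a shared
variance. Given μ₀, minimizing the model SSE decomposes additively over
segments — the cost of segment [i, j) is −(s₁ − n_c μ₀)²/n_c with s₁ and
n_c the sum and count of its triangle cells — so for every boundary
budget K the optimum over all placements with **at most K** internal
boundaries is found exactly by dynamic programming. The budgeted reading
makes the log-likelihood curve non-decreasing in K by construction;
under the exact-K reading it provably is not (splitting a block
surrenders its cross cells to the off-block mean). μ₀ is profiled:
initialized from far-from-diagonal cells (distance ≥ n/2), then
re-estimated once from the off-block cells of the first DP partition and
the DP re-run.

Per-boundary gains are assigned by forward selection *within* the final
boundary set: each step adds the member boundary that maximizes the
log-likelihood increase, and its gain is that increase. The border
filter then ranks boundaries by gain, finds the elbow of the sorted gain
curve (maximum perpendicular distance to the chord joining its first and
last points), treats the boundaries past the elbow as the "linear
portion", and removes the lowest 10% (configurable) of that portion,
breaking gain ties by genomic position with the leftmost kept. Both the
fraction and the elbow rule are configuration-exposed, as the notion of
"linear portion" admits alternatives.

Default boundary budget: bins/15 (mean segment ≥ 150 kb at 10-kb bins),
configurable. The DP is quadratic per budget step; chromosome arms at
10 kb (a few thousand bins) segment in seconds.

## Boundary correspondence

Nearest-border distances are computed per chromosome between any two
border sets (domain borders vs TAD boundaries, band borders vs domain
borders), in either direction. Chromosome-end borders are excluded by
default — the comparison concerns internal boundaries. "Within one
10-kb bin" is reported as distance ≤ 10 kb (primary); the
same-or-adjacent-bin reading (≤ 20 kb worst case) can be obtained by
passing that tolerance.

## Domain annotation and profiles

Genes are represented by their TSS; features in unassigned gaps are
reported separately and excluded from the D/E denominator, so D + E
fractions sum to 1 over assigned features. Expression breadth counts
conditions with score **strictly** greater than the threshold (default
300 on the tiling-array score scale).

Scaled-domain profiles split each domain into 80 tiles plus 10 flank
tiles per side of the same width; a feature at position p maps to tile
⌊(p − start)/width⌋, clamped inside the domain. Flank tiles of one
domain may overlap neighbouring domains — no exclusion is applied, so a
feature can appear in one domain's body and another's flank. Summit
counts are scaled by 1000/n (n = class total genome-wide), which makes
profiles of classes with different abundances comparable: proportionally
identical placements give identical scaled profiles (a test identity).
Domains shorter than 80 bp (tile width < 1 bp) are skipped and counted.

Accumulation profiles around anchors scale counts by 1000/n, divide by
the anchor count, then map the profile affinely so its minimum is 0 and
maximum 10. Both raw and scaled values are returned, since the affine
map discards level information.

Band overlays rescale each band (length filter: > 75 kb) to 200 kb,
append 50-kb unscaled flanks, and report the fraction of bands covered
by D, E, or neither at each sampled position (1-kb steps); off-chromosome
positions count as neither. The three fractions sum to 1 everywhere.

## Interaction-distance analysis

Per 5-kb anchor bin, interactions to partners within 1 Mb are collected
and normalized to sum 1; the short fraction is the mass at distances in
[5 kb, 50 kb] (self-interactions below 5 kb remain in the total but not
in the numerator), the long fraction the mass in (50 kb, 500 kb].
Anchors within 1 Mb of a chromosome end, with zero total, or with raw
total above the 97.5th percentile (computed genome-wide by default;
per-chromosome behind a flag) are masked.

The per-domain distance profile collects normalized values of bin pairs
lying **entirely inside** each domain longer than 30 kb, keyed by
distance; medians per 10-kb distance bin are compared between D and E
with a two-sided rank-sum test on the per-distance medians. Because the
test pools medians across distances (both labels decay), it is
conservative for paired shifts; it is reported as specified rather than
replaced by a paired test. Note that under coverage-product
normalization the within-E block enrichment largely cancels (expected
scales with r_E²), so on pipeline-normalized synthetic matrices the D/E
median ordering is not a reliable readout of the planted enrichment; the
operation's correctness is therefore asserted against directly
constructed matrices (uniform elevated E blocks over a power-law
background), where E medians are flat, D medians follow the planted
power law, and D < E at mid-range.

## D-D corner hotspots

Eligible E domains are ≥ 60 kb with D domains *immediately* adjacent on
both sides (an unassigned gap disqualifies — "flanked" is read
literally). The corner rectangle couples the left-flank D bins with the
right-flank D bins, each side truncated to the 10 bins nearest the E
domain to keep the region local. Densities are measured on the
distance-normalized matrix (each cell divided by the genome-wide mean at
its distance), and the corner is called a hotspot when its density
exceeds 1.1 × the neighbour density.

The neighbour density estimate is the one genuinely open design point.
Same-shape rectangles shifted along the genome at matched distance land
on E-touching cells, which coverage-product normalization systematically
depresses (~1.5-fold under the generator's conditions) — that comparison
calls essentially every corner a hotspot. The default therefore compares
like with like: the corner rectangles of the nearest eligible E domains
(up to two per side), which match the corner in both composition (D-D)
and, after distance normalization, in decay. Because roughly a third of
those neighbours carry hotspots themselves, candidates exceeding 1.5 ×
the smallest candidate are trimmed before averaging, and the local
estimate is floored at the genome-wide median corner density (the
local-vs-global background rule familiar from peak calling; the median
is robust while hotspot-bearing corners remain a minority). The
genomic-shift and one-bin-ring alternatives remain available via
`neighbour_mode`.

Under the default synthetic conditions (2× planted corners, 35% planting
rate) this detector's true-positive rate is ≈ 0.95 and its
false-positive rate ≈ 3–5%, so the detected fraction tracks the planted
rate within a few percentage points.

## Synthetic-data generators

All generators are pure functions of (config, seed), with independent
RNG streams per generator. Defaults, chosen once for desk-scale realism:

| parameter | default | rationale |
|---|---|---|
| bin width | 1 kb | ChIP track resolution |
| emission means | −0.3 / +0.6 | log₂-ratio scale; ~3 pooled-SD separation |
| emission SDs | 0.25 / 0.35 | enriched state noisier |
| stay probabilities | 0.98 / 0.98 | 50-kb mean domain length at 1-kb bins |
| Hi-C resolution | 10 kb | matrix bin width |
| decay exponent | 1.0 | contact probability ∝ 1/(1+d) |
| background | 100 | counts at distance 0; deep-coverage regime |
| E-block factor | 3 | within-E enrichment |
| hotspot factor / rate | 2 / 0.35 | planted corner strength and frequency |
| coverage-bias SD | 0.1 | lognormal per-bin bias |
| feature classes | tss: 4000 @ 0.62, housekeeping: 1200 @ 0.95 | D-placement probabilities |
| band jitter SD | 9 kb | ⇒ ~90% of band borders within 15 kb of an E border |
| expression threshold | 300 | expressed/unexpressed cut on the score scale |

Contact counts are Poisson (not negative binomial): the downstream
statistics are ratios and medians, insensitive to overdispersion, and no
dispersion structure is asserted anywhere. Matrices are sampled on the
upper triangle and mirrored, so they are exactly symmetric.

What the generators do **not** emulate — and hence what passing tests do
not demonstrate about real data: spatial autocorrelation of array noise,
restriction-fragment structure and ligation artefacts, overdispersed
contact counts, distance-decay differences between D and E domains
(both decay with the same exponent), nested/hierarchical TADs,
trans-chromosomal contacts, and copy-number or mappability biases.
Conclusions supported by the synthetic loop are about the correctness
and calibration of the estimators under their stated model, not about
biology.

## Problem sizes

The test suite and the acceptance script use desk-scale problems chosen
to keep estimates well inside their tolerance bands: 50,000 bins for HMM
parameter recovery, a 20-Mb two-chromosome genome for the end-to-end
loop, 500-bin matrices for TAD recovery, and three 2,700-bin chromosomes
(~450 eligible E domains) for hotspot calibration. Everything runs in
about a minute on one CPU.

## Known limitations

* The two-state HMM absorbs true domains of 1–2 bins into their
  neighbours (the Viterbi path correctly favours the prior at that
  scale); border recovery saturates around 90–95% under the default
  domain-length distribution for this reason.
* The exact DP is quadratic in bins per budget step; very long
  chromosomes at fine resolution (≫10⁴ bins) would need windowing.
* The border filter's "linear portion" is an operationalization (chord
  elbow); different elbow rules move a handful of borderline boundaries.
* `fit_two_state_hmm` requires ≥ 100 non-missing bins per chromosome;
  tiny scaffolds should be excluded or pooled.
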