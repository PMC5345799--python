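# dedomains

Segmentation of a genome into H3K27me3-**D**epleted and -**E**nriched
chromatin domains, and the statistics that relate this two-state partition
to three-dimensional genome architecture.

In *Drosophila*, the genome-wide H3K27me3 profile is close to binary:
domains with very low or absent H3K27me3 (D domains) are packed with
housekeeping genes and architectural proteins such as BEAF-32 and
Chromator, while domains with moderate-to-high H3K27me3 (E domains) hold
regulated genes and correspond to the prominent interaction-dense TADs of
the Hi-C contact map. D domains sit between TADs, their borders coincide
with TAD boundaries and with polytene band borders, and the two D domains
flanking an E-domain TAD often touch, producing a "corner" of elevated
D-D interaction atop the TAD triangle.

`dedomains` implements that entire analysis as a tested pipeline,
exercisable end to end on synthetic data with known ground truth. It is a
library first (every stage is a plain function over in-memory containers)
with a thin `dedomains` CLI for file-to-file runs.

## What it computes

**ChIP preprocessing** (`dedomains.chip`) — per-channel median scaling to
500, quantile normalization across channels, replicate averaging, 1-kb
binning by mean probe score, TSS ±500 bp median enrichment per gene
class, and the relative class-position statistic (housekeeping mean = 0,
Polycomb-target mean = 1).

**HMM segmentation** (`dedomains.hmm`) — per chromosome, a two-state
hidden Markov model with Gaussian emissions

&nbsp;&nbsp;&nbsp;&nbsp;*x*ₜ | *z*ₜ = *k* ~ N(μₖ, σₖ²), *z*ₜ a 2-state Markov chain,

fitted by expectation-maximization, decoded by the Viterbi path
(posterior decoding optional), the lower-mean state labelled D; equal
adjacent states merge into regions and probe gaps flanked by the same
state are closed.

**Hi-C** (`dedomains.hic`, `dedomains.tads`) — binning of valid pairs at
10 kb, observed/expected normalization under the binomial
coverage-product model (expectedᵢⱼ = 2 rᵢ rⱼ N with rᵢ the relative
coverage of bin i), and TAD calling by exact dynamic-programming block
segmentation of the log-scale matrix (block-constant diagonal means over
a shared off-block mean), with the weakest 10% of the linear portion of
the ranked boundary log-likelihood gains removed.

**Architecture statistics** (`dedomains.boundaries`, `.annotate`,
`.profiles`, `.interactions`) — nearest-border distance distributions and
fraction-within summaries, per-class feature fractions in D/E, chromatin
state composition, expression-breadth splits, 80-tile scaled-domain
profiles with 1000/n summit scaling, 0–10 accumulation profiles, scaled
polytene-band overlays, short- (5–50 kb) vs long-range (50–500 kb)
interaction fractions per 5-kb bin, per-domain interaction
distance-decay medians, and D-D corner hotspot detection (corner density
more than 1.1-fold above matched neighbouring corners).

**Synthetic data** (`dedomains.simulate`) — generators mirroring all of
the above with known truth: a two-state Gaussian-emission chain per 1-kb
bin, Poisson contact matrices with power-law decay, E-domain blocks,
planted D-D corner hotspots and coverage bias, D-biased feature
placement, and band sets with jittered E borders.

## Worked example

```python
import numpy as np
from dedomains import (
    Genome, SimulationConfig, simulate_chip_track, simulate_features,
    segment_track, assign_points, BorderSet, nearest_border_distances,
    fraction_within,
)

genome = Genome.from_dict({"chr2L": 10_000_000})
cfg = SimulationConfig(genome=genome, seed=7)
track, truth = simulate_chip_track(cfg)

domains, fits = segment_track(track, seed=7)
params = fits["chr2L"].params
print(f"emission means: D={min(params.means):+.3f}  E={max(params.means):+.3f}")
print(f"stay probabilities: {params.stay_probabilities[0]:.3f}, {params.stay_probabilities[1]:.3f}")
print(f"domains called: {len(domains.domains('D'))} D, {len(domains.domains('E'))} E")

dists = nearest_border_distances(
    BorderSet.from_domain_map(domains), BorderSet.from_domain_map(truth)
)
print(f"borders within 1 kb of truth: {100*fraction_within(dists, 1000):.1f}%")

features = simulate_features(cfg, truth)
table = assign_points(features, domains)
for _, row in table.iterrows():
    print(f"{row['class']}: {100*row.frac_d:.1f}% of TSSs in D domains")
```

prints

```
emission means: D=-0.302  E=+0.608
stay probabilities: 0.980, 0.976
domains called: 103 D, 103 E
borders within 1 kb of truth: 98.5%
housekeeping: 94.7% of TSSs in D domains
tss: 61.5% of TSSs in D domains
```

The fitted emission means and stay probabilities recover the generator's
truth (−0.3/+0.6, 0.98); 98.5% of called D/E borders fall within one
1-kb bin of a true border; and the feature classes land in D domains at
their configured placement rates (0.95 for the housekeeping class, 0.62
for all TSSs).

The same pipeline runs from the shell over text files (bedGraph, BED,
chrom.sizes, pair tables, matrix triplets):

```
dedomains simulate --chrom-sizes chrom.sizes --out-dir sim --seed 7
dedomains hmm-segment --chrom-sizes chrom.sizes --track sim/chip.bedgraph --out domains.bed
dedomains hic-normalize --matrix sim/hic_chr2L.counts.txt --out norm.txt
dedomains hic-segment --matrix norm.txt --out tads.bed
dedomains boundary-match --chrom-sizes chrom.sizes --query tads.bed --reference domains.bed --out match.tsv
```

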