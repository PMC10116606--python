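# Methods

## Demographic and selection model

A diploid population of size N (default 10,000) is founded at generation 0
by a single admixture pulse: each founder haplotype is drawn from source 1
with probability m (default 0.5) and source 2 otherwise, as one unbroken
ancestry tract. The population then mates randomly (selfing allowed) for G
generations (default 50) in discrete Wright–Fisher fashion. Population size
can change on a schedule (`SizeEvent`: set-size, bottleneck start/end),
evaluated before each offspring generation is drawn.

Selection acts on one or more biallelic sites. Source 1 carries the
beneficial allele at frequency `p_source1` (default 1.0, i.e. a perfect
ancestry-informative marker) and source 2 at `p_source2` (default 0.0).
Fitness is multiplicative over sites: genotype fitness 1 + s (homozygous
carrier), 1 + hs (heterozygote, default h = 0.5), 1 (non-carrier). Parents
are drawn with probability proportional to fitness (fecundity selection).
There is no mutation: allele and ancestry dynamics are driven entirely by
the founding pulse, drift, recombination and selection.

The `F_ST = 0` scenario sets `p_source1 = p_source2 = 0.5`: the allele can
still sweep, but carries no ancestry information, so ancestry-based methods
should see nothing. This is implemented exactly (alleles are tracked
separately from tracts and copied through meiosis), not approximated.

## Recombination and ancestry tracts

Each haplotype is an ordered tiling of [0, L) by half-open tracts labeled
with source ancestry. Meiosis draws a Poisson(rL) number of crossovers
(default r = 1.3e-8 per bp per gamete; L = 50 Mb gives mean 0.65) at
uniform positions, or, with a genetic-map table, a Poisson(total map
length in Morgans) count at positions uniform in map distance and
transformed back to bp by interpolation. The gamete walks alternating
parental haplotypes between breakpoints, merging same-ancestry junctions.
The inner loop is a `numba` kernel operating on flat concatenated arrays
(ends + int8 ancestries + offsets), which keeps 10,000-diploid, 50-
generation simulations at well under a second per replicate.

Validated invariants: exact tract tiling after arbitrary runs; Poisson
crossover counts (chi-square against the exact pmf); neutral ancestry is a
martingale; the deterministic selection recursion
p' = p[p(1+s) + q(1+hs)] / w̄ is recovered at large N (p0 = 0.5, s = 0.5,
h = 0.5 gives p1 = 0.55).

## Painting

A sample of n haplotypes (default 200, drawn as n/2 diploids without
replacement) becomes an n x W binary image (default W = 200): row = haplotype,
column = genomic interval, pixel 1 ("black") = majority ancestry from
source 1 over that interval, length-weighted and computed exactly by
interpolating the cumulative ancestry-1 length at pixel boundaries. Exact
50/50 ties (tolerance 1e-9 of a pixel) take the ancestry at the interval
midpoint. PNG output uses 0 = black, 255 = white.

Column layout is physical (bp) by default; in genetic mode positions are
first transformed through the recombination map so pixels are equally
spaced in cM. AIM mode reduces each haplotype to a step function over a
fixed marker panel (default 100 uniform positions, drawn once per model
and reused): every position takes the ancestry of the nearest marker at or
to its left.

The training annotation for a selected variant is a full-height box of
2·half_width + 1 pixels (default 11) centered on the variant's pixel,
clamped at image edges; e.g. a variant at 77% of a 50 Mb chromosome on a
200-pixel axis yields [150, 0, 161, 200]. Variants are placed uniformly in
the central 90% of the chromosome so the target stays on-image.

## Detector

The detector follows the two-stage object-detection contract: propose
candidate regions, score each with the probability it contains a selected
variant, suppress overlaps, report detections with score strictly above
the threshold (default 0.5).

The built-in backbone is a sliding-window detector designed for CPU-only
training: every x-pixel is a candidate box center; its features are the
column-mean (per-column black fraction) profile in a ±25-pixel window
(edge-padded), centered by the image-wide mean so peak shape rather than
absolute ancestry level drives the score, plus the image-wide mean and SD.
A `GradientBoostingClassifier` (depth 3, learning rate 0.1,
`epochs × 5` boosting stages, seeded) is trained on the variant center ± 1
as positives and random far-from-target centers as negatives, with the
highest-contrast columns of neutral images as hard negatives. Training
logs the per-stage log-loss and aborts on non-finite values.

At inference, score-profile local maxima (minimum separation of one box
width) are refined to the score-weighted centroid of the contiguous
near-peak plateau (within 5% of the peak): confident classifiers produce
near-flat plateaus across the selected region, and the leftmost-argmax
convention would otherwise systematically place boxes at the plateau edge
(~6 pixels off); the refinement centers them on the signal. IoU-0.5
non-maximum suppression guards against residual duplicates. Any other
backbone implementing `fit(examples, config)` / `score_profile(pixels)`
can be plugged in; the config carries the usual neural-training fields
(epochs, base_lr, weight_decay, frozen_epochs) for such backbones.

## Evaluation

Every x-pixel of every image is a binary test: positive when covered by a
reported detection, true when inside the target box — so a perfect
detection of an 11-pixel target on a 200-pixel image contributes 11 TP and
189 TN. Counts are pooled across images before computing precision and
recall; a no-skill detector covering everything has precision 11/200. The
PR curve sweeps 10,000 evenly spaced thresholds on [0, 1] with strict
`score > t`, sorts points by recall, extends to recall 0 at the maximum
observed precision, and integrates by the trapezoid rule. The bbox
detection rate is the fraction of all predicted boxes whose x-range
contains the true variant pixel (boxes on neutral images count in the
denominator). Box-width and per-image box-count summaries use the sample
variance (n − 1).

## Outlier-scan baseline

Each chromosome is binned into 200 equal windows; a window's statistic is
the length-weighted mean ancestry-1 proportion over sampled haplotypes. A
window is flagged when it deviates from the genome-wide window mean by
more than z (default 3) genome-wide population standard deviations,
two-sided by default. Truth for scoring is an 11-window region centered on
the variant's window, mirroring the detector's pixel target. On
five-chromosome 50 Mb genomes the scan shows the expected pattern: recall
near 0.9, precision near 0.5 — it finds the region but flags wide
shoulders.

## Problem sizes and profiles

`pipeline.PROFILES` defines two scales: `paper` (8,000 training / 2,000
validation images, 30 epochs) approximating a full study-scale run, and
`desk` (400/100, 10 epochs) sized for a single CPU in minutes. Acceptance
checks (`tests/test_acceptance.py`, `scripts/acceptance.py`) run the desk
profile; at that scale the bbox detection rate on held-out baseline images
is ≈ 0.9 and rises with training budget.

## Numerical and reproducibility choices

- All randomness flows from user seeds via `numpy` sequence seeding:
  image i of a run with base seed s uses `default_rng((s, i))`, so datasets
  are byte-identical across reruns and train/validation seeds are disjoint
  by index offset.
- Parent sampling uses a cumulative-sum + binary-search draw; crossover
  sorting happens inside the meiosis kernel (per-gamete insertion sort on
  typically ≤ 3 breakpoints).
- Rasterization and window means share one primitive: interpolation of the
  cumulative ancestry-1 length at interval boundaries, anchored at
  position 0, which is exact for piecewise-constant tracts.
- Artifacts carry provenance: config hashes, seeds, and manifests in
  sorted-key JSON.

## Limitations

- Two source populations only, one admixture pulse, no ongoing migration
  and no mutation; local ancestry is assumed known without error (painting
  consumes true simulated tracts, not inferred ancestry).
- The built-in backbone sees only column-mean profiles; haplotype-level
  texture (row structure, tract-length decay) is invisible to it. It
  reaches study-like detection rates at desk scale but is not a neural
  detector and its scores are not calibrated probabilities.
- Detection boxes have fixed width (the training target width), so the
  reported box width carries no information about sweep extent.
- Fecundity selection with selfing slightly differs from models that
  forbid selfing; at N ≥ 1,000 the effect is negligible for the
  quantities reported here.
- The outlier scan assumes approximately constant ancestry variance across
  windows; demographies with strong drift (small N, long G) widen the
  null and depress its recall.
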