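# Methods

This note records the models, rules and numerical choices behind
`cadkit`, and what the synthetic benchmarks do and do not demonstrate.

## Signal model and normalization

The unit of analysis is a peak set (0-based half-open intervals, BED
convention) with a peaks × samples count matrix over T ordered stages,
two conditions and R replicates. Counts are converted to RPKM,

    rpkm = count · 10⁹ / (peak_length_bp · library_size),

with library sizes supplied by the caller (read alignment and counting
are upstream of this package). "Normalized signal" for all trajectory
work means log2(RPKM + 1); the pseudocount keeps closed loci finite and
compresses replicate noise at low coverage. Replicates are averaged on
the RPKM scale before any thresholding, since the open/closed decision
is about the stage-level mean, not any single library.

## Trajectory classification

A peak is *open* at a stage when its stage-mean RPKM is ≥ 2.0 (the
boundary value counts as open; both the threshold and the boundary rule
are configurable). The resulting binary sequence of length T receives
exactly one label:

- no switch → `stable_open` / `stable_closed`;
- one switch → `OC_k` (open at stages 1..k, closed after) or `CO_k`
  (closed at stages 1..k, open after), where k is the **last stage in
  the original state** — with stages [MEF, day0, day1, day3, day5,
  day7], CO1/CO2/CO3 peaks open at day0/day1/day3;
- two or more switches → `complex`.

Multi-switch trajectories are kept out of the OC/CO counts rather than
forced into the class of their first switch; this keeps class
semantics exact and auditable at the cost of a `complex` bucket that
grows with noise. For length-6 sequences the partition is 2 stable,
5 OC, 5 CO and 52 complex — a useful census check. Raising the open
threshold can only move stages from open to closed, so labels move
monotonically toward `stable_closed`, never back.

## Gradually closed regions

The GCR threshold is θ = f · (global max − global min) of the
normalized matrix, with f = 0.05. The range is **global** (whole
matrix), not per-peak: a per-peak range would make θ incomparable
across peaks and would mark any monotone decline, however shallow, as
gradual closing.

The phrase "signal differences between adjacent stages relative to a
threshold" admits two readings, and both are implemented as modes:

- `monotone_min_step` (default): s_t − s_{t+1} ≥ θ for every adjacent
  pair — strictly step-wise closing, every step substantial;
- `literal_max_step`: monotone non-increasing, every per-step drop
  ≤ θ, and total drop ≥ a configurable minimum (default θ) — gradual
  in the sense of "no abrupt step".

Under the default mode GCR sets are nested in θ (larger θ, smaller
set). Membership is called on a reference condition (the control); the
mean normalized trajectory of that member set is then reported for
*every* condition, so a knockdown that slows closing shows up as an
elevated curve at intermediate stages. A sign test over per-peak
(knockdown − control) differences at intermediate stages makes that
readout quantitative.

Known limitation: with the default simulation's noise (NB dispersion
0.05, two replicates) the late-stage drops of a planted log-linear
decline sit close to θ, so the strict all-steps rule recalls only a
minority (~15–20%) of planted gradually-closing peaks. The rule is
precise rather than sensitive; the delay readout does not depend on
high recall because the called set is still a faithful sample of
closing loci.

## Density comparison without replicates

For per-region signals x, y in two conditions (pseudocount c = 0.5):

    M = log2((x+c)/(y+c)),  A = ½·log2((x+c)(y+c)).

A linear bias model M = a + b·A is fitted to common regions by OLS,
then refitted on the middle 80% of residuals so genuinely changed
regions do not drag the line. Rescaled M is the residual from that
line; the bias-corrected y is the value that reproduces the residual
on the raw scale. Significance comes from the exact conditional
Poisson test (x | x + y_corrected ~ Binomial(·, ½) under equal rates),
two-sided. A region is `increased` when rescaled M ≥ 1 and p ≤ 0.01,
`decreased` symmetrically, else `no_change`. The construction makes
calls invariant to a global rescaling of y, which the synthetic
generator exercises with a deliberate 2-fold offset.

This is a self-contained re-implementation of the M-A rescale-and-test
idea for replicate-free comparisons; it is not claimed to match any
external tool's output number for number. With 10⁴ equal-mean Poisson
pairs the non-`no_change` rate is ~0.1–0.2% (bounded well under
2·p_cutoff); planted 4-fold increases at Gamma(2, 50) baselines are
recovered with ≥ 99% sensitivity and precision.

## SOM trajectory grouping

Trajectories are row-standardized (mean 0, sd 1; constant rows dropped
with a warning) and clustered by an online SOM on a rectangular grid
(default 1×6, matching six pattern groups). Per step: draw a row, find
the best-matching unit (minimum Euclidean distance, ties to the lowest
node index), and pull every node toward the row with Gaussian
neighborhood weight around the BMU. Learning rate and radius decay
exponentially from lr₀ = 0.5 and σ₀ = (max grid dim)/2 to lr = 0.01
and σ = 0.2 at the final step — a coarse ordering phase followed by
near-k-means convergence; with σ forced to 0 the update *is* online
k-means, which the tests verify against a k-means oracle. Node weights
are initialized from data rows sampled without replacement, and all
randomness flows from the config seed, so training is bit-reproducible.

Node numbering on the grid is arbitrary, so reported cluster names
G1..GK are ordered by the stage of each cluster's mean-trajectory
extremum (then by sign), which keeps group names stable across
training seeds.

The archetype benchmark plants six canonical patterns — up-early,
up-late, down-early, down-late, transient-up, flat — **on the z-score
scale** (each pattern standardized to mean 0, sd 1; flat is the zero
vector), because that is the scale the clustering operates on, with
Gaussian noise sd 0.3. Recovery is measured by adjusted Rand index;
both the SOM and a k-means reference reach ARI 1.0 under these
conditions.

## Annotation and integration

Promoters are strand-aware ±2 kb windows around the TSS (the window is
configurable; common annotation tools default to ±3 kb — the choice is
stamped into outputs). The minus-strand window is the exact coordinate
mirror of the plus-strand one, a property the tests check directly.
A peak reports every gene it touches, promoter taking precedence over
gene body per gene; nearest-TSS assignment (signed distance, ties to
the lexicographically smallest gene id) serves the "annotated nearest
gene" style of analysis. Region-class gene sets are cross-tabbed
against expression groups with a one-sided hypergeometric
over-representation test per cell (universe = genes carrying at least
one peak) and BH correction across cells; the enrichment test is an
addition beyond simple counting and is labelled as such in outputs.
An audit table links every counted gene back through
class → peak → gene → group.

## Synthetic study conditions

Defaults: 5000 peaks of 500 bp on a 3×10 Mb toy genome with ≥ 1.5 kb
spacing; stages [MEF, day0, day1, day3, day5, day7]; class mix 15%
stable_open, 15% stable_closed, 25% spread evenly over OC1–OC5, 25%
over CO1–CO5, 10% gradually-closing, 10% complex; open state 8 RPKM
and closed 0.5 RPKM (4× separation between open and the 2-RPKM
boundary); NB dispersion 0.05 with 2 replicates at 10⁷ reads; the
knockdown delays 30% of closing (OC and GCR) peaks by one stage;
density vectors use Gamma(2, 50) baselines, a 10% planted 4-fold
increased set, a 2-fold global y offset, and Poisson sampling; one
gene per non-complex peak with TSS at the peak center and expression
an affine map (offset 4, gain 0.5) of log2 accessibility plus Gaussian
noise (sd 0.3). Mean counts are rpkm·length·library/10⁹, so RPKM
normalization inverts the construction in expectation.

What the generator does **not** emulate: mappability and GC bias,
peak-width variation, fragment-length structure, batch effects between
replicates, overlapping genes, enhancer–gene links beyond the one
planted TSS, and the fat-tailed library-size variation of real
experiments. Passing benchmarks therefore show the algorithms are
correct and well calibrated under their stated model, not that real
data meet that model.

## Numerical and procedural choices

- Percentile bootstrap (not BCa), default 1000 resamples, seed
  mandatory; bands at the (1±level)/2 quantiles of per-stage means
  over row resamples.
- Metaprofile windows are ±3 kb around the interval midpoint (or
  narrowPeak summit on request) in 50 bp bins; out-of-bounds windows
  are dropped with a warning rather than zero-padded.
- Interval overlap means ≥ 1 shared base; half-open book-ended
  intervals do not overlap (min_overlap_bp = 0 fuses them on request).
- Degenerate inputs fail loudly: inverted BED coordinates name the
  line, constant matrices warn with θ = 0, an M-A fit with no A
  variance raises, a single-row bootstrap raises.
- Pipeline outputs carry a provenance header (version, config hash,
  seed); the hash covers the scientific configuration and excludes the
  output path, so identical analyses produce identical bytes anywhere.
- Benchmarks in the test suite run at reduced sizes (hundreds to a few
  thousand peaks; 10⁴ regions for null calibration; 200 bootstrap
  repeats), chosen as the smallest sizes at which the measured rates
  are stable against their thresholds.
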