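# cadkit

Chromatin accessibility dynamics (CAD) analysis for reprogramming-style
time courses. During somatic-cell reprogramming, thousands of open
somatic loci must close while pluripotency loci open; chromatin
remodeling complexes such as NuRD drive the closing arm, and knocking
their subunits down leaves somatic chromatin open too long. `cadkit`
provides the computational half of that analysis for anyone with a peak
set and a peaks × samples count matrix over an ordered series of stages
(e.g. MEF, day0, day1, day3, day5, day7):

- **Open/close trajectory classification.** RPKM-normalize counts,
  binarize at an openness boundary (default 2 RPKM, at-boundary counts
  as open), and label each peak `stable_open`, `stable_closed`,
  `OC_k` (open through stage *k*, closed after), `CO_k` (the reverse),
  or `complex` (more than one switch).
- **Gradually closed regions (GCRs).** On the normalized scale
  s = log2(RPKM+1), a peak is a GCR when every adjacent-stage drop
  s_t − s_{t+1} ≥ θ, with θ = 0.05 × (global signal range). The mean
  GCR trajectory per condition is the readout for delayed closing.
- **Replicate-free density comparison.** For two conditions with
  per-region signals x, y: M = log2((x+c)/(y+c)),
  A = ½·log2((x+c)(y+c)); a robust line M = a + b·A fitted on common
  regions removes global bias, and regions are called
  increased / decreased / no_change by |rescaled M| ≥ 1 with an exact
  conditional Poisson test at p ≤ 0.01.
- **SOM trajectory grouping.** An online self-organizing map (1×6 grid
  by default) clusters z-scored trajectories into stable, ordered
  pattern groups G1–G6.
- **Peak→gene integration.** Promoter (±2 kb) / gene-body annotation,
  nearest-TSS assignment, and region-class × expression-group
  crosstabs with hypergeometric enrichment.
- **Synthetic data with planted truth.** A generator emulating a
  two-condition six-stage experiment — negative-binomial replicate
  noise, planted trajectory classes, a knockdown that closes loci one
  stage late, planted density changes, and expression coupled to
  promoter accessibility — so every stage is testable end to end.

Supporting utilities include interval algebra (merge / intersect /
nearest over BED and narrowPeak), metaprofiles around peak centers
(±3 kb, 50 bp bins), percentile-bootstrap confidence bands for mean
trajectories, and Benjamini–Hochberg adjustment.

## Worked example

```python
import cadkit as ck

cfg = ck.SimConfig(n_peaks=2000, seed=2)
peaks = ck.simulate_peaks(cfg)
counts, truth = ck.simulate_timecourse(cfg, peaks)
logm = ck.log_transform(ck.rpkm_normalize(counts, peaks.lengths()))

result = ck.detect_gcr(logm)
print(f"theta = {result.theta:.3f}   GCR peaks (control): {len(result.members)}")
print(result.mean_trajectories.round(3))
```

prints

```
theta = 0.217   GCR peaks (control): 43

             MEF   day0   day1   day3   day5   day7
condition
control    3.191  2.490  1.890  1.339  0.896  0.440
knockdown  3.110  2.671  1.997  1.460  0.956  0.644
```

θ is 5% of the global normalized-signal range; 43 control peaks close
step-wise by at least θ at every stage transition. The knockdown's
mean trajectory over those same peaks sits above the control's at every
intermediate stage (day0–day5): the planted 30% closing delay shows up
exactly as slower loss of accessibility at somatic loci. The scripts in
`examples/` walk through each capability the same way (classification,
density comparison, SOM groups, integration, full pipeline), and
`cadkit run-all --out out/ --seed 6` runs everything from the shell.

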