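"""Classify per-peak open/close trajectories over a reprogramming time course.

Simulates a small two-condition ATAC-seq count matrix with planted
trajectory classes, RPKM-normalizes it, binarizes at the 2-RPKM
boundary and labels every peak as stable_open / stable_closed / OC_k /
CO_k / complex.  OC_k means the locus was open through stage k and
closed afterwards; CO_k the reverse.
"""

import cadkit as ck

cfg = ck.SimConfig(n_peaks=1000, seed=1)
peaks = ck.simulate_peaks(cfg)
counts, truth = ck.simulate_timecourse(cfg, peaks)

rpkm = ck.rpkm_normalize(counts, peaks.lengths())
labels, summary = ck.classify_all(rpkm, condition="control")

print("trajectory class counts (control):")
print(summary.to_string())

mask = truth.peaks["class"].str.match("OC|CO|stable")
recovery = (truth.peaks.loc[mask, "class"] == labels.loc[mask, "label"]).mean()
print(f"\nplanted-label recovery: {100 * recovery:.1f}%")
print(
    "# Each peak's RPKM trajectory was thresholded at 2 (>= 2 is open) and\n"
    "# labeled by its single open/closed switch; recovery close to 100%\n"
    "# means replicate noise rarely crosses the boundary."
)
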