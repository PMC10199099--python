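"""Detect gradually closed regions and the knockdown-delay readout.

GCRs are peaks whose normalized (log2 RPKM+1) signal drops by at least
theta = 0.05 x (global signal range) between every pair of adjacent
stages.  The simulation delays closing for 30% of closing loci in the
knockdown condition, so the knockdown's mean GCR trajectory should sit
above the control's at intermediate stages — chromatin that fails to
close on schedule.
"""

import cadkit as ck

cfg = ck.SimConfig(n_peaks=2000, seed=2)
peaks = ck.simulate_peaks(cfg)
counts, truth = ck.simulate_timecourse(cfg, peaks)
logm = ck.log_transform(ck.rpkm_normalize(counts, peaks.lengths()))

result = ck.detect_gcr(logm)
print(f"theta = {result.theta:.3f}   GCR peaks (control): {len(result.members)}")
print("\nmean normalized signal of the GCR set per condition:")
print(result.mean_trajectories.round(3).to_string())

inter = result.mean_trajectories.columns[1:-1]
above = (
    result.mean_trajectories.loc["knockdown", inter]
    > result.mean_trajectories.loc["control", inter]
)
print(
    f"\nknockdown above control at {int(above.sum())}/{len(inter)} "
    "intermediate stages"
)
print(
    "# A knockdown curve lying above the control at intermediate stages is\n"
    "# the quantitative signature of slower closing of somatic loci."
)
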