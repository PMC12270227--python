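"""CP Activity Scores and the three activity-threshold methods.

The CP score is the mean of squared HistDiff feature scores.  Wells above
a control-derived threshold are called phenotypically active; three
methods (IQR outlier exclusion, top-5% FDR exclusion, elbow knee) give
different cut-offs on the same control distribution.
"""

import numpy as np

import cpscreen as cp

print("CP score of fingerprint (3, 4):", cp.cp_activity_score([3.0, 4.0]))
print("  ((9 + 16) / 2 = 12.5: mean of squared feature scores)")

rng = np.random.default_rng(0)
controls = rng.lognormal(mean=-8.0, sigma=0.4, size=128)  # null-like CP scores
all_wells = np.concatenate([controls, rng.lognormal(-6.5, 0.8, size=300)])

iqr = cp.threshold_iqr(controls)
fdr = cp.threshold_fdr(controls)
elbow = cp.threshold_elbow(np.sort(all_wells))
for thr in (iqr, fdr, elbow):
    print(f"{thr.method:>6} threshold: {thr.value:.3e}")
print("  (IQR is the most conservative here: it drops every control above Q3;")
print("   the elbow uses all well scores, not just controls)")

active = float((all_wells[128:] > fdr.value).mean())
print(f"wells called active at the FDR-5% threshold: {100 * active:.1f}%")
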