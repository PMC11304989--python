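"""FROC scoring and the competition performance metric on a toy system.

A candidate is a true positive when its center falls inside a truth's
bounding sphere (radius diameter/2); the FROC curve reports sensitivity
against false positives per scan, and the CPM averages sensitivity at
0.125, 0.25, 0.5, 1, 2, 4 and 8 FP/scan.
"""

import numpy as np

from nodulefpr.froc import (
    CPM_FP_RATES,
    bootstrap_cpm_diff,
    cpm,
    froc_curve,
    match_detections,
    random_baseline,
)
from nodulefpr.volumes import AnnotationRecord, Candidate

rng = np.random.default_rng(0)
truths, candidates = [], []
for s in range(20):
    scan = f"scan-{s:02d}"
    truths.append(AnnotationRecord(scan, (50.0, 50.0, 20.0), 10.0))
    # a good system: the hit scores high, 30 false candidates score lower
    candidates.append(Candidate(scan, (51.0, 50.0, 20.0),
                                score=float(rng.uniform(0.6, 1.0))))
    for _ in range(30):
        candidates.append(
            Candidate(scan, (float(rng.uniform(0, 100)), 10.0, 5.0),
                      score=float(rng.uniform(0.0, 0.7)))
        )

detections = match_detections(candidates, truths)
froc = froc_curve(detections, n_scans=20, n_truths=len(truths))
print("sensitivity at the seven CPM rates:")
for f, s in zip(CPM_FP_RATES, froc.cpm_sensitivities):
    print(f"  {f:6.3f} FP/scan -> {s:.3f}")
print(f"CPM = {froc.cpm:.3f} (mean of the seven)")

rand = match_detections(random_baseline(candidates, seed=1), truths)
rand_froc = froc_curve(rand, n_scans=20, n_truths=len(truths))
print(f"random-score baseline CPM = {rand_froc.cpm:.3f} "
      "(≈ f/N for N candidates/scan)")

lo, hi = bootstrap_cpm_diff(detections, rand, truths, n_boot=500, seed=2)
print(f"95% bootstrap CI of the CPM difference: [{lo:.3f}, {hi:.3f}] — "
      "scans are resampled, both systems re-scored per replicate.")
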