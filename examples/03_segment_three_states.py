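"""CER segmentation of trajectories that switch between three mobility states.

Simulates trajectories alternating between Gaussian-step states with scale
ratios 1:3:10, segments them with consecutive escape radii, fits the
shared-width step-size mixture and prints the weight matrix and mixing score.
"""

import numpy as np

from subdiff import (ThresholdSet, fit_shared_gaussian_mixture,
                     pooled_steps_by_state, scan_thresholds,
                     select_threshold_sets, segment_ensemble)
from subdiff.trackio import Trajectory, TrajectoryEnsemble

rng = np.random.default_rng(0)
sigmas = (10.0, 30.0, 100.0)     # per-coordinate step std per state, nm
trajs = []
for i in range(60):
    state = int(rng.integers(0, 3))
    xy = np.zeros((600, 2))
    for t in range(1, 600):
        if rng.random() < 1 / 200:               # mean dwell 200 frames
            state = int((state + rng.integers(1, 3)) % 3)
        xy[t] = xy[t - 1] + rng.standard_normal(2) * sigmas[state]
    trajs.append(Trajectory(id=i, frames=np.arange(600), xy=xy))
ens = TrajectoryEnsemble(trajs, frame_interval=1 / 85)

sets = [ThresholdSet([R, 150.0], [10, 5]) for R in (50.0, 70.0, 90.0)]
results = scan_thresholds(ens, sets)
for r in results:
    print(f"R_th={r.thresholds.R_th} n_th={r.thresholds.n_th} "
          f"score={r.score:.3f} segments={list(r.meta['n_segments'])}")

accepted, failures = select_threshold_sets(results, min_Rth=40.0,
                                           diag_min=0.9, count_min=10)
best = max(accepted, key=lambda r: r.fit.score)
print(f"\nbest accepted set: R_th={best.thresholds.R_th}")
print(f"fitted component widths (nm): {best.fit.sigmas.round(1)}")
print("weight matrix (rows = components, columns = subpopulations):")
print(best.fit.weights.round(3))
print(f"mixing score: {best.fit.score:.3f} (maximum 3.0)")

print("\nA near-identity weight matrix means each segmented subpopulation is "
      "described by a\nsingle Gaussian step-size component — the signature of "
      "a clean separation into\ndistinct mobility states.")
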