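"""Link a localization table into trajectories and reject immobile particles.

Builds a localization table of two mobile and three immobile (pure
localization-noise) particles, links it frame by frame with the optimal
assignment, and applies the Rg / mean-step immobile filter.
"""

import numpy as np
import pandas as pd

from subdiff import LinkingConfig, compute_dmax, immobile_filter, link_trajectories

rng = np.random.default_rng(0)
rows = []
# two mobile particles (Brownian, 30 nm rms steps), well separated
for start in ([0.0, 0.0], [5000.0, 5000.0]):
    xy = np.asarray(start) + np.cumsum(rng.standard_normal((80, 2)) * 30.0, axis=0)
    rows += [(f, x, y, 800.0, 25.0) for f, (x, y) in enumerate(xy)]
# three immobile particles: apparent motion is localization noise only
for start in ([2000.0, 500.0], [500.0, 2500.0], [3500.0, 1500.0]):
    xy = np.asarray(start) + rng.standard_normal((80, 2)) * 25.0
    rows += [(f, x, y, 400.0, 25.0) for f, (x, y) in enumerate(xy)]

table = pd.DataFrame(rows, columns=["frame", "x", "y", "intensity", "uncertainty"])
print(f"d_max for D = 0.5 um^2/s at 85 fps: {compute_dmax(0.5e-12, 85.0):.1f} nm")

ensemble = link_trajectories(table, LinkingConfig(d_max=300.0, min_length=50))
mobile, immobile, summaries = immobile_filter(ensemble, threshold=2.11)
print(f"linked {len(ensemble)} tracks -> {len(mobile)} mobile, "
      f"{len(immobile)} immobile")
for s in summaries:
    print(f"  track {s.track_id}: Rg={s.Rg:7.1f} nm  <|dr|>={s.mean_step:6.1f} nm "
          f" ratio={s.normalized_ratio:5.2f}  mobile={s.mobile}")

print("\nFor pure localization noise the normalised Rg/<|dr|> ratio is ~1 "
      "regardless of the\nnoise level; genuinely moving particles exceed the "
      "2.11 threshold.")
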