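"""Profile GC composition across MDS-IES boundaries.

Builds 2,000 synthetic boundaries with a 40-bp somatic-destined (MDS) flank
at GC 0.41 and a 40-bp germline-limited (IES) flank at GC 0.29, then runs
the 3-bp / 2-bp sliding-window profiler. The printed shift is the mean
window GC over the 20 bp on the MDS side minus the IES side, in percentage
points — the compositional step that demarcates germline-soma boundaries.
"""

import numpy as np

from scramblescan.composition import BoundaryContext, boundary_profile, boundary_shift
from scramblescan.sequtil import random_sequence

rng = np.random.default_rng(7)
scaffolds = {
    f"b{i}": random_sequence(rng, 40, 0.41) + random_sequence(rng, 40, 0.29)
    for i in range(2000)
}
bounds = [BoundaryContext(sid, 40, "left") for sid in scaffolds]

profile = boundary_profile(bounds, scaffolds, flank=40, window=3, step=2)

print("rel_pos  mean_gc  95% CI")
for rel, m, lo, hi in zip(
    profile.rel_positions, profile.mean_gc, profile.ci95_low, profile.ci95_high
):
    if abs(rel) <= 6:
        print(f"{rel:7.1f}  {m:.3f}   [{lo:.3f}, {hi:.3f}]")

shift_pp = 100 * boundary_shift(profile, span=20)
print(f"\nboundary GC shift: {shift_pp:.2f} percentage points")
# Negative positions are the MDS side (GC-rich), positive the IES side
# (GC-poor); the shift recovers the planted 12-point compartment contrast.
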