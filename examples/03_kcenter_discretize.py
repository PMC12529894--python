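"""k-center discretization of continuous features.

Farthest-first traversal picks centers that cover the data with the
smallest worst-case radius (within a factor 2 of optimal); every frame is
then labelled by its nearest center.  The cover radius reported on the
model is the guarantee: no training point is farther than that from its
assigned center.
"""

import numpy as np

from trajgpt import assign, k_center_cluster

rng = np.random.default_rng(0)
# three well-separated 2-D clusters standing in for conformational basins
blobs = np.concatenate([
    rng.normal([0, 0], 0.3, (300, 2)),
    rng.normal([4, 0], 0.3, (300, 2)),
    rng.normal([2, 3], 0.3, (300, 2)),
])

for k in (3, 6, 12):
    model = k_center_cluster(blobs, k=k, seed=1)
    print(f"k={k:>2}: cover_radius={model.cover_radius:.3f}")
# the cover radius shrinks as k grows; at k=3 each basin gets one center

model = k_center_cluster(blobs, k=3, seed=1)
traj = assign(blobs, model)
print("\nframes per state at k=3:", np.bincount(traj.states).tolist())
print("centers:\n", np.round(model.centers, 2))
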