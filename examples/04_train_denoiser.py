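"""Train a residual U-net DRF denoiser on thinned calibration replicates.

Builds the paired training set (20 independent 10% thinnings of the
full-count measurement, x10 magnitude-matched), groups DRFs by
sensitivity, and trains one small network on the dimmest group.  Prints
the per-epoch loss so the convergence behaviour is visible.

Runs a deliberately small configuration (~2 min on one CPU core); scale
``base_channels``/epochs up for real use.
"""

import numpy as np

from gammacal.denoise import make_training_set
from gammacal.detector import DetectorGeometry, SourceSpec, sample_counts, simulate_true_sm
from gammacal.geometry import AngularGrid, make_coarse_grid
from gammacal.grouping import kmeans_group
from gammacal.nn import NetworkSpec, TrainConfig, train
from gammacal.sm import interpolate_coarse_to_fine

geometry = DetectorGeometry(n_transverse=8, n_depth_bins=3, sub_block_size=4)
source = SourceSpec("Tc99m", mu=0.19, events_per_point=1e5)
fine_grid = AngularGrid(np.arange(0.0, 91.0, 6.0), np.arange(0.0, 359.0, 6.0))

fc_coarse = sample_counts(simulate_true_sm(geometry, source, make_coarse_grid()), seed=0)
fc_fine = interpolate_coarse_to_fine(fc_coarse, fine_grid)
assignment = kmeans_group(fc_fine.bin_totals(), k=3, seed=0)
print("group sizes:", assignment.group_sizes.tolist())

ts = make_training_set(fc_coarse, n_replicates=20, fraction=0.1, fine_grid=fine_grid)
sub = ts.restrict(assignment.members(3))
print(f"group 3 training pairs: {len(sub)} of {len(ts)} "
      f"(padded image shape {sub.inputs.shape[1:]})")

model = train(
    sub.inputs, sub.labels,
    TrainConfig(epochs=5, seed=0),
    NetworkSpec(variant="res_unet", base_channels=4),
    group=3, source_label=source.label,
)
print("epoch losses:", [f"{v:.4f}" for v in model.loss_history])
# The residual network starts at the identity map (epoch-1 loss equals the
# raw noise level) and learns the correction; losses fall monotonically.
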