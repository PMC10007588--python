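"""Simulate the calibration measurement of a 3D position-sensitive detector.

Builds the attenuation-based detector model, simulates the noiseless
system matrix on the 10-degree calibration grid, draws a Poisson full-count
measurement, and prints the sensitivity structure that drives everything
downstream: surface layers shield deep layers, and sub-block-edge bins lose
split events to the energy window.
"""

import numpy as np

from gammacal.detector import DetectorGeometry, SourceSpec, sample_counts, simulate_true_sm
from gammacal.geometry import make_coarse_grid
from gammacal.grouping import sensitivity_map

# 16x16x5 bins, GAGG-like attenuation at ~140 keV, 20% edge loss emulating
# energy-window rejection of events split across read-out sub-blocks
geometry = DetectorGeometry(edge_loss=0.8)
source = SourceSpec("Tc99m", mu=0.19, events_per_point=1e6)
grid = make_coarse_grid()

true_sm = simulate_true_sm(geometry, source, grid)
fc = sample_counts(true_sm, seed=0)

print(f"coarse system matrix: {fc.values.shape[0]} pixels x {fc.values.shape[1]} bins")
sens = sensitivity_map(fc, geometry)  # (16, 16, 5) lattice of DRF totals
layer_means = sens.mean(axis=(0, 1))
print("mean sensitivity per depth layer (1 = surface):")
for i, m in enumerate(layer_means, 1):
    print(f"  layer {i}: {m:12.0f} counts")
edge = geometry.edge_mask()
print(f"sub-block-edge bins: {sens.ravel()[edge].mean():.0f} counts on average")
print(f"interior bins:       {sens.ravel()[~edge].mean():.0f} counts on average")
# The surface layer dominates at 140 keV and the edge bins sit visibly
# below the interior: exactly the non-uniformity the grouping step targets.
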