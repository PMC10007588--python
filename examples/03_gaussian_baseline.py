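"""Baseline denoising: per-DRF Gaussian filtering with a swept kernel width.

A 10%-acquisition (low-count) system matrix is magnitude-matched (x10) and
each DRF is filtered with the sigma in [0.1, 15.0] pixels minimising the
mean square error against the full-count reference.  Prints the sweep for
one bin and the SM-level SSIM before and after.
"""

from gammacal.detector import DetectorGeometry, SourceSpec, sample_counts, simulate_true_sm, thin_counts
from gammacal.evaluate import ssim_sm
from gammacal.gaussian import gaussian_denoise_sm, optimize_sigma
from gammacal.geometry import AngularGrid, make_coarse_grid
from gammacal.sm import extract_drf, interpolate_coarse_to_fine

import numpy as np

# reduced detector so the example runs in seconds
geometry = DetectorGeometry(n_transverse=8, n_depth_bins=3, sub_block_size=4)
source = SourceSpec("Tc99m", mu=0.19, events_per_point=1e5)
fine_grid = AngularGrid(np.arange(0.0, 91.0, 6.0), np.arange(0.0, 359.0, 6.0))

fc_coarse = sample_counts(simulate_true_sm(geometry, source, make_coarse_grid()), seed=0)
fc = interpolate_coarse_to_fine(fc_coarse, fine_grid)
lc = interpolate_coarse_to_fine(thin_counts(fc_coarse, 0.1, seed=1), fine_grid).scaled(10.0)

sweep = optimize_sigma(extract_drf(lc, 100), extract_drf(fc, 100))
print(f"bin 100: optimal sigma = {sweep.sigma_opt:.1f} px "
      f"(MSE {sweep.mse_curve.min():.1f} vs {sweep.mse_curve[-1]:.1f} at sigma=15)")

gdsm = gaussian_denoise_sm(lc, fc)
print(f"SSIM vs full-count SM:  low-count {ssim_sm(lc, fc):.4f}  ->  "
      f"Gaussian-denoised {ssim_sm(gdsm, fc):.4f}")
# The optimally filtered SM is structurally much closer to the full-count
# reference; this is the bar the learned denoisers have to clear.
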