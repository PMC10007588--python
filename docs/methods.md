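# Methods

## The problem

Collimator-less gamma imagers built around a single 3D position-sensitive
scintillator block reconstruct the direction of radiation sources from the
*self-attenuation* of the block: a photon arriving from direction (θ, φ)
is preferentially absorbed in the bins facing that direction, so the
histogram of detected events over the 16×16×5 detector bins encodes the
source direction.  Reconstruction is MLEM with an experimentally measured
system matrix (SM): the point source is stepped over a 10°×10° grid of the
hemisphere (360 positions), the 360×1280 count matrix is spline-interpolated
to a 1° grid (32 760 × 1280), and each column — a detector response
function (DRF), a 360×91 image over (φ, θ) — is the angular fingerprint of
one bin.

Accurate calibration needs long acquisitions.  The package implements and
evaluates the alternative: measure 10% of the events, and denoise the
resulting low-count SM (LC-SM) DRF-by-DRF with per-sensitivity-group
encoder–decoder networks, against a tuned Gaussian filter as baseline and
the full-count SM (FC-SM) as reference.

## Synthetic detector model

No measured calibration data are available, so a ray-traced attenuation
model generates them.  For bin *j* and source direction **d** (parallel
rays; the ~0.9 m source distance dwarfs the ~70 mm block, making the
far-field error O(block/distance) ≈ 4%):

    p_j(d) = exp(−μ·L_up) · (1 − exp(−μ·L_self)) · edge_factor_j · jitter_j

where `L_self` is the chord of the ray through bin *j*'s box, `L_up` the
in-block path upstream of the bin (slab-method ray–box intersections), and
μ the linear attenuation coefficient at the source energy.  μ is a config
entry to be taken from standard attenuation tables for the scintillator
(defaults: 0.19 mm⁻¹ for a ~140 keV source, 0.046 mm⁻¹ for ~662 keV).
`edge_factor` (default 0.8) phenomenologically emulates energy-window
rejection of events split across read-out sub-blocks — it produces the
characteristic "cross" sensitivity pattern without modelling Compton
transport.  `jitter` is a per-bin log-normal efficiency fingerprint
(median 1, log-sd 0.2 by default) that distinguishes physical devices for
inter-device studies.

The noiseless SM scales each direction's probability vector so every
calibration point contributes the same expected event total (fixed-exposure
protocol).  Poisson sampling gives the full-count measurement; binomial
thinning with p = 0.1 — exactly equivalent to uniform list-mode
subsampling — gives 10%-acquisition replicates.

**What the simulator does not emulate:** Compton scatter and energy
spectra, scintillation-light transport and SiPM/ASIC response, depth-bin
cross-talk, dead time, and the room/background field.  Passing tests
therefore demonstrate that the *pipeline* behaves as designed on data with
realistic structure (depth/edge sensitivity non-uniformity, Poisson
statistics, device mismatch), not that the physics model is complete.

## Pipeline

1. **DRF decomposition.**  SM columns reshape losslessly to (φ, θ) images;
   assembly is the exact inverse.  Interpolation is per-bin bicubic
   (`RectBivariateSpline`) with periodic φ extension and natural θ ends;
   negative overshoot is clipped to zero.
2. **Grouping.**  Per-bin totals (sensitivities) are clustered by 1-D
   K-means (Euclidean distance, k-means++ ×10 restarts, seeded, labels
   sorted by descending centroid), k = 3 by default.  One denoiser is
   trained per group because the optimal denoising parameters track the
   count level.
3. **Gaussian baseline.**  Per DRF, σ ∈ {0.1, …, 15.0} pixels (step 0.1)
   is swept and the MSE against the full-count DRF minimised; ties break
   toward less smoothing.  Choosing σ against the reference makes the
   baseline best-case.  Boundaries: wrap in φ, reflect in θ; kernel
   truncated at 4σ and renormalised.
4. **Learned denoisers.**  U-net: four encoder stacks (2 same-padded 3×3
   convolutions + ReLU, 2×2/2 max-pool), two-conv bottleneck, four decoder
   stacks (2×2/2 transposed convolution, skip concatenation, 2 convs),
   final 1×1 convolution; channel width doubles from `base_channels`
   (64 at full scale).  Res-U-net adds a global input→output skip.
   Inputs are DRFs zero-padded to multiples of 16 (360×91 → 368×96),
   ×10-scaled to full-count magnitude.  Training: MSE, Adam, batch 16,
   lr 1e-4 with ×0.996 per-epoch decay, fixed per-(source, group) epoch
   budgets at full scale.  The training set is 20 independent thinnings of
   the full-count measurement (20 × 1280 = 25 600 pairs at full scale);
   test thinnings use disjoint seed streams.
5. **Inter-device transfer.**  Per-bin count ratios F_j =
   (device-1 total)/(device-2 total) scale the second device's DRFs to the
   training count level before the network and are divided out after;
   with identical devices the path is bit-exactly the intra-device one.
6. **Evaluation.**  SM-level SSIM is the unweighted mean of per-DRF SSIM
   (11×11 Gaussian window, σ=1.5, K1=0.01, K2=0.03, dynamic range = the
   reference DRF's maximum; the window shrinks for images smaller than 11
   pixels).  Positioning bias is the great-circle angle between the true
   direction and the intensity centroid (θ̂, φ̂) of the MLEM image; FWHM
   resolution is √(FWHM_θ² + FWHM_φ²) from an axis-aligned anisotropic
   Gaussian fit with constant offset, FWHM = 2√(2 ln 2)·σ.  The harness
   images a point source at the 36 positions θ∈{17,35,46,53,64,81}° ×
   φ∈{64,82,127,189,261,333}°, 10⁶ events and 10 000 MLEM iterations per
   image at full scale, and summarises mean/SD over repeated test SMs
   (the single full-count dataset has no SD).

## Numerical and design choices

- **Bias formula.**  The centroid-based position estimate is a (θ̂, φ̂)
  pair; the bias is defined here as the great-circle separation of the
  corresponding unit vectors, which gives the deviation a physical angular
  meaning.  A literal planar arccos of the normalised 2-tuples is kept as
  `mode="planar"` for audits.  The φ centroid is the plain linear mean by
  default (the standard test positions avoid the 0°/360° wrap); a
  circular-mean mode is available and is unbiased across the wrap.
- **MLEM.**  Plain multiplicative updates, uniform positive start, no
  subsets/regularisation/stopping rule; 0/0 ratios resolve to 0; pixels
  with zero sensitivity leave the support; zero-column bins are dropped
  from the update with a warning.
- **Residual-branch init.**  The final 1×1 convolution of the Res-U-net is
  zero-initialised so the network starts exactly at the identity map and
  learns only the noise correction; with lr 1e-4 this removes a long
  burn-in from a randomly initialised output layer.  The plain U-net keeps
  variance-scaling init throughout.
- **Input normalisation.**  Each training set is divided by one scalar
  (its mean label value), stored with the model and inverted at
  application; the optimiser then sees order-one pixels at any count
  level.  The scalar commutes with the residual skip and with the
  inter-device scaling.
- **Padding.**  Zero fill, content centred (368×96 places the 360×91
  content at offset (4, 2)); crop inverts pad bit-exactly and padding
  preserves totals.
- **Spline boundary.**  φ is circular (periodic extension before
  fitting); θ = 0°/90° are physical FOV edges (natural spline ends).
- **Negative outputs** of the networks are clipped at zero on assembly —
  SM entries are counts.
- **Seeds.**  One master seed fans out through a named, append-only
  substream registry (measurement, training thinnings, test thinnings,
  device fingerprints, training, evaluation), so runs are reproducible
  and adding a stage never shifts earlier draws.

## Desk-scale study conditions

The full-scale configuration (16×16×5 bins, 1° grid, width-64 networks,
Table-budget epochs, 10⁴ MLEM iterations) is supported but takes GPU-scale
effort.  The package's reference study — used by the test suite and the
acceptance script — scales the geometry down while keeping every protocol
step: 8×8×3 bins (192 DRFs, 2×2 sub-blocks), 6° fine grid (16×60 pixels,
DRFs padded to 64×16), 10⁵ expected events per calibration point,
20 training + 5 testing thinnings at 10%, width-4 Res-U-nets trained 30
epochs (the training loss plateaus by then at this scale), and the same
36 test positions reconstructed with 300 MLEM iterations at 10⁵ events.
Absolute figures (bias of a few degrees, resolution of tens of degrees)
reflect the much smaller detector and coarser grid; the comparisons
between SM variants are the meaningful output.

## Known limitations

- The simulator's idealisations above; in particular the edge "cross" is
  phenomenological, not a scatter model.
- Group sizes and absolute SSIM/bias/resolution levels measured on real
  instruments depend on hardware properties the simulator only sketches;
  only orderings and directions of effects transfer.
- The Gaussian baseline's σ is chosen against the full-count reference,
  which is generous to the baseline and unavailable in deployment.
- 1-D K-means with k-means++ restarts is not guaranteed globally optimal
  in general (it is verified optimal on small instances by enumeration).
- The linear φ centroid is biased for sources within a few image FWHM of
  the φ wrap; use the circular mode there.
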