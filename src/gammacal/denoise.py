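"""Dataset preparation and application of the learned DRF denoisers.

Protocol (intra-device):

1. Acquire a full-count system matrix (FC-SM) and thin its events to 10%
   ``n_replicates`` times (default 20), giving independent low-count SMs.
2. Scale every low-count DRF by 1/fraction (x10) to match the full-count
   magnitude; pad to network dimensions.
3. Train one network per (source, sensitivity group) on all replicates'
   (scaled low-count DRF, full-count DRF) pairs.
4. Denoise an unseen low-count SM by routing each DRF through its group's
   network, cropping, clipping negatives, and re-assembling: the U-DSM /
   R-DSM.

Inter-device: a second imager's count levels differ per bin, so its DRFs
are first multiplied by the count-ratio factors F_j (device-1 total over
device-2 total), denoised with device-1 networks, divided by F_j again and
re-assembled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import thin_counts
from .grouping import GroupAssignment
from .nn import NetworkSpec, TrainConfig, TrainedDenoiser, train
from .sm import (
    DRFImage,
    ScalingFactors,
    SystemMatrix,
    apply_scaling,
    assemble_sm,
    crop_image,
    extract_drf,
    invert_scaling,
    pad_image,
)

__all__ = [
    "TrainingSet",
    "make_training_set",
    "train_group_models",
    "denoise_sm",
    "inter_device_denoise",
]


@dataclass
class TrainingSet:
    """Padded (input, label) image stacks plus the bin index of each pair."""

    inputs: np.ndarray  # (M, H, W), low-count DRFs scaled to FC magnitude
    labels: np.ndarray  # (M, H, W), full-count DRFs
    bin_indices: np.ndarray  # (M,)
    pad_offset: tuple[int, int]
    original_shape: tuple[int, int]

    def restrict(self, bins: np.ndarray) -> "TrainingSet":
        """Pairs whose bin index lies in ``bins`` (one DRF group)."""
        mask = np.isin(self.bin_indices, bins)
        return TrainingSet(
            self.inputs[mask], self.labels[mask], self.bin_indices[mask],
            self.pad_offset, self.original_shape,
        )

    def __len__(self) -> int:
        return self.inputs.shape[0]


def _padded_drf_stack(sm: SystemMatrix) -> tuple[np.ndarray, tuple, tuple]:
    imgs = []
    off = shape = None
    for j in range(sm.n_bins):
        drf = extract_drf(sm, j)
        padded, off = pad_image(drf.image)
        shape = drf.shape
        imgs.append(padded)
    return np.stack(imgs), off, shape


def make_training_set(
    fc_sm: SystemMatrix,
    n_replicates: int = 20,
    fraction: float = 0.1,
    seeds=None,
    fine_grid=None,
) -> TrainingSet:
    """Build the paired training set by repeated event thinning.

    ``seeds`` must provide one entry per replicate (defaults to 0..n-1);
    keep them disjoint from any testing thinnings.  Each replicate's
    low-count DRFs are scaled by 1/fraction so input and label magnitudes
    match in expectation.

    With ``fine_grid`` set, ``fc_sm`` is the coarse integer-count
    calibration measurement: thinning happens on the measured counts (the
    list-mode stage) and both thinned and full matrices are spline-
    interpolated onto ``fine_grid`` before DRF extraction, mirroring the
    calibration chain.
    """
    from .sm import interpolate_coarse_to_fine

    if seeds is None:
        seeds = list(range(n_replicates))
    if len(seeds) != n_replicates:
        raise ValueError("need one seed per replicate")

    def to_images(sm):
        if fine_grid is not None:
            sm = interpolate_coarse_to_fine(sm, fine_grid)
        return _padded_drf_stack(sm)

    labels, off, shape = to_images(fc_sm)
    inputs = []
    for s in seeds:
        lc = thin_counts(fc_sm, fraction, seed=s)
        stack, _, _ = to_images(lc.scaled(1.0 / fraction))
        inputs.append(stack)
    n_bins = fc_sm.n_bins
    return TrainingSet(
        inputs=np.concatenate(inputs, axis=0),
        labels=np.tile(labels, (n_replicates, 1, 1)),
        bin_indices=np.tile(np.arange(n_bins), n_replicates),
        pad_offset=off,
        original_shape=shape,
    )


def train_group_models(
    training_set: TrainingSet,
    assignment: GroupAssignment,
    spec: NetworkSpec,
    config: TrainConfig,
    source_label: str | None = None,
    epochs_by_group: dict[int, int] | None = None,
) -> dict[int, TrainedDenoiser]:
    """Train one denoiser per sensitivity group.

    ``epochs_by_group`` overrides the config's epoch count per group (the
    fixed per-group budgets of the full-scale protocol); group seeds are
    derived from the config seed so groups train independently.
    """
    from dataclasses import replace

    models: dict[int, TrainedDenoiser] = {}
    for group in range(1, assignment.k + 1):
        subset = training_set.restrict(assignment.members(group))
        if len(subset) == 0:
            raise ValueError(f"group {group} has no training pairs")
        cfg = config
        if epochs_by_group and group in epochs_by_group:
            cfg = replace(cfg, epochs=epochs_by_group[group])
        if cfg.seed is not None:
            cfg = replace(cfg, seed=int(np.random.SeedSequence([cfg.seed, group]).generate_state(1)[0] % (2**31)))
        models[group] = train(
            subset.inputs, subset.labels, cfg, spec,
            group=group, source_label=source_label,
        )
    return models


def denoise_sm(
    models_by_group: dict[int, TrainedDenoiser],
    lc_sm: SystemMatrix,
    assignment: GroupAssignment,
    batch_size: int = 32,
) -> SystemMatrix:
    """Denoise a magnitude-matched low-count SM with the per-group networks.

    Every DRF is padded, passed through its group's model, cropped back,
    clipped at zero (SM entries are counts) and re-assembled.
    """
    if assignment.labels.size != lc_sm.n_bins:
        raise ValueError("assignment does not match system-matrix bin count")
    missing = [g for g in range(1, assignment.k + 1) if g not in models_by_group]
    if missing:
        raise ValueError(f"no model for group(s) {missing}")
    stack, off, shape = _padded_drf_stack(lc_sm)
    out = np.empty_like(stack)
    for group in range(1, assignment.k + 1):
        bins = assignment.members(group)
        model = models_by_group[group]
        for start in range(0, bins.size, batch_size):
            sel = bins[start : start + batch_size]
            out[sel] = model(stack[sel])
    drfs = [
        DRFImage(np.clip(crop_image(out[j], shape, off), 0.0, None), j)
        for j in range(lc_sm.n_bins)
    ]
    meta = dict(lc_sm.metadata, denoiser=next(iter(models_by_group.values())).spec.variant)
    return assemble_sm(drfs, lc_sm.grid, metadata=meta)


def inter_device_denoise(
    models_dev1: dict[int, TrainedDenoiser],
    lc_sm_dev2: SystemMatrix,
    fc_totals_dev1: np.ndarray,
    assignment: GroupAssignment,
) -> SystemMatrix:
    """Denoise a second device's low-count SM with first-device networks.

    The five scaling steps: (1) per-bin factors F_j = device-1 total /
    device-2 total, (2) multiply device-2 DRFs by F_j, (3) denoise with
    device-1 models, (4) divide the outputs by F_j, (5) re-assemble.
    """
    totals2 = lc_sm_dev2.bin_totals()
    zero = np.flatnonzero(totals2 <= 0)
    if zero.size:
        raise ValueError(f"device-2 DRF total is zero for bin(s) {zero[:5].tolist()}")
    factors = ScalingFactors(np.asarray(fc_totals_dev1, float) / totals2)
    scaled = apply_scaling(lc_sm_dev2, factors)
    denoised = denoise_sm(models_dev1, scaled, assignment)
    return invert_scaling(denoised, factors)
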