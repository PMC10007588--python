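"""End-to-end calibration experiments: simulate, group, denoise, evaluate.

A :class:`PipelineConfig` describes one complete study — detector and
source, calibration grids, thinning protocol, denoiser settings and the
evaluation — with a single master seed fanned out to named substreams so
that adding a stage never perturbs the draws of earlier stages.

Two presets are provided: :func:`full_scale_config` mirrors the physical
instrument (16x16x5 bins, 1-degree grid, 10,000 MLEM iterations, fixed
per-group epoch budgets), and :func:`desk_scale_config` is a reduced study
(8x8x3 bins, 5-degree grid) whose every protocol step is identical but
which runs on a laptop CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .denoise import denoise_sm, make_training_set, train_group_models
from .detector import DetectorGeometry, SourceSpec, sample_counts, simulate_true_sm, thin_counts
from .gaussian import gaussian_denoise_sm
from .geometry import AngularGrid, make_coarse_grid, make_fine_grid
from .grouping import GroupAssignment, kmeans_group
from .nn import NetworkSpec, TrainConfig, table_epochs
from .evaluate import run_evaluation, ssim_sm, summarize_evaluation, test_positions
from .sm import SystemMatrix, interpolate_coarse_to_fine

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "full_scale_config",
    "desk_scale_config",
    "seed_for",
    "simulate_calibration",
    "run_pipeline",
]

# Named substreams derived from the master seed.  The registry is append-only:
# new stages get new names, existing draws never shift.
_SEED_REGISTRY = {
    "fc_counts": 11,
    "train_thinning": 23,
    "test_thinning": 37,
    "device2": 41,
    "training": 53,
    "evaluation": 67,
}


def seed_for(master_seed: int, stream: str, index: int = 0) -> int:
    """Deterministic child seed for a named substream of the master seed."""
    if stream not in _SEED_REGISTRY:
        raise KeyError(f"unknown seed stream '{stream}'")
    ss = np.random.SeedSequence([int(master_seed), _SEED_REGISTRY[stream], int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    # detector / source
    n_transverse: int = 16
    n_depth_bins: int = 5
    sub_block_size: int = 8
    crystal_pitch: float = 4.05
    crystal_depth: float = 20.0
    mu: float = 0.19  # 1/mm at the source energy (attenuation-table value)
    edge_loss: float = 0.8
    source_label: str = "Tc99m"
    events_per_point: float = 1.0e7
    # calibration grids
    fine_step_theta: float = 1.0
    fine_step_phi: float = 1.0
    # thinning protocol
    fraction: float = 0.1
    n_train_replicates: int = 20
    n_test_replicates: int = 10
    # grouping
    k_groups: int = 3
    # learned denoiser
    variant: str = "res_unet"
    base_channels: int = 64
    epochs: int | None = None  # None -> per-group table budgets
    batch_size: int = 16
    initial_lr: float = 1e-4
    lr_decay: float = 0.996
    # evaluation
    n_events: int = 1_000_000
    n_iter: int = 10_000
    # reproducibility
    master_seed: int = 0

    def geometry(self) -> DetectorGeometry:
        return DetectorGeometry(
            n_transverse=self.n_transverse,
            n_depth_bins=self.n_depth_bins,
            sub_block_size=self.sub_block_size,
            crystal_pitch=self.crystal_pitch,
            crystal_depth=self.crystal_depth,
            mu=self.mu,
            edge_loss=self.edge_loss,
        )

    def source(self) -> SourceSpec:
        return SourceSpec(self.source_label, mu=self.mu, events_per_point=self.events_per_point)

    def fine_grid(self) -> AngularGrid:
        if self.fine_step_theta == 1.0 and self.fine_step_phi == 1.0:
            return make_fine_grid()
        return AngularGrid(
            np.arange(0.0, 90.0 + 1e-9, self.fine_step_theta),
            np.arange(0.0, 360.0 - 1e-9, self.fine_step_phi),
        )

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(variant=self.variant, base_channels=self.base_channels)

    def epochs_by_group(self) -> dict[int, int]:
        if self.epochs is not None:
            return {g: self.epochs for g in range(1, self.k_groups + 1)}
        return {
            g: table_epochs(self.variant, self.source_label, g)
            for g in range(1, self.k_groups + 1)
        }

    def to_dict(self) -> dict:
        return asdict(self)


def full_scale_config(master_seed: int = 0, **overrides) -> PipelineConfig:
    """The physical-instrument study conditions."""
    return PipelineConfig(master_seed=master_seed, **overrides)


def desk_scale_config(master_seed: int = 0, **overrides) -> PipelineConfig:
    """Reduced study for CPU runs: 8x8x3 detector (192 bins), 6-degree fine
    grid (16 x 60 pixels), 1e5 events per calibration point, 5 test SMs,
    base width 4, 30-epoch budget (training loss plateaus by then at this
    scale), 300 MLEM iterations at 1e5 events per test projection.
    Protocol structure is unchanged."""
    params = dict(
        n_transverse=8,
        n_depth_bins=3,
        sub_block_size=4,
        events_per_point=1.0e5,
        fine_step_theta=6.0,
        fine_step_phi=6.0,
        n_test_replicates=5,
        base_channels=4,
        epochs=30,
        n_events=100_000,
        n_iter=300,
    )
    params.update(overrides)
    return PipelineConfig(master_seed=master_seed, **params)


@dataclass
class CalibrationData:
    """Simulated calibration measurements for one device."""

    geometry: DetectorGeometry
    true_sm: SystemMatrix  # noiseless expectation, coarse grid
    fc_coarse: SystemMatrix  # Poisson full-count measurement, coarse grid
    fc_fine: SystemMatrix  # interpolated full-count SM
    lc_fine_test: list  # interpolated, x(1/fraction)-scaled test low-count SMs


def simulate_calibration(config: PipelineConfig, device_geometry=None, seed_offset: int = 0) -> CalibrationData:
    """Simulate the calibration measurement chain for one device."""
    geometry = device_geometry if device_geometry is not None else config.geometry()
    source = config.source()
    coarse = make_coarse_grid()
    fine = config.fine_grid()
    true_sm = simulate_true_sm(geometry, source, coarse)
    fc_coarse = sample_counts(true_sm, seed=seed_for(config.master_seed, "fc_counts", seed_offset))
    fc_fine = interpolate_coarse_to_fine(fc_coarse, fine)
    lc_test = []
    for i in range(config.n_test_replicates):
        s = seed_for(config.master_seed, "test_thinning", 1000 * seed_offset + i)
        lc = thin_counts(fc_coarse, config.fraction, seed=s)
        lc_fine = interpolate_coarse_to_fine(lc, fine).scaled(1.0 / config.fraction)
        lc_test.append(lc_fine)
    return CalibrationData(geometry, true_sm, fc_coarse, fc_fine, lc_test)


@dataclass
class PipelineResult:
    config: PipelineConfig
    data: CalibrationData
    assignment: GroupAssignment
    models: dict
    gdsm: list
    dnn_dsm: list
    ssim: dict
    eval_records: "object" = None  # pandas DataFrame
    eval_summary: "object" = None
    loss_histories: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    evaluate_positions: bool = True,
    variants_to_evaluate: tuple = ("FC", "LC", "G-DSM", "DNN-DSM"),
) -> PipelineResult:
    """Run the complete intra-device study described by ``config``.

    Produces the full-count reference, test low-count SMs, the Gaussian
    baseline (G-DSM) and network-denoised (U-DSM/R-DSM) variants, SM-level
    SSIM for each, and — unless disabled — the 36-position bias/resolution
    evaluation.
    """
    data = simulate_calibration(config)
    fine = config.fine_grid()

    sens = data.fc_fine.bin_totals()
    assignment = kmeans_group(sens, k=config.k_groups, seed=config.master_seed)

    train_seeds = [
        seed_for(config.master_seed, "train_thinning", i)
        for i in range(config.n_train_replicates)
    ]
    training_set = make_training_set(
        data.fc_coarse,
        n_replicates=config.n_train_replicates,
        fraction=config.fraction,
        seeds=train_seeds,
        fine_grid=fine,
    )
    train_cfg = TrainConfig(
        batch_size=config.batch_size,
        initial_lr=config.initial_lr,
        lr_decay=config.lr_decay,
        epochs=1,  # overridden per group below
        seed=seed_for(config.master_seed, "training"),
    )
    models = train_group_models(
        training_set,
        assignment,
        config.network_spec(),
        train_cfg,
        source_label=config.source_label,
        epochs_by_group=config.epochs_by_group(),
    )

    gdsm = [gaussian_denoise_sm(lc, data.fc_fine) for lc in data.lc_fine_test]
    dnn = [denoise_sm(models, lc, assignment) for lc in data.lc_fine_test]

    ssim = {
        "LC": float(np.mean([ssim_sm(lc, data.fc_fine) for lc in data.lc_fine_test])),
        "G-DSM": float(np.mean([ssim_sm(g, data.fc_fine) for g in gdsm])),
        "DNN-DSM": float(np.mean([ssim_sm(d, data.fc_fine) for d in dnn])),
    }

    result = PipelineResult(
        config=config,
        data=data,
        assignment=assignment,
        models=models,
        gdsm=gdsm,
        dnn_dsm=dnn,
        ssim=ssim,
        loss_histories={g: m.loss_history for g, m in models.items()},
    )

    if evaluate_positions:
        variant_sms = {
            "FC": [data.fc_fine],
            "LC": data.lc_fine_test,
            "G-DSM": gdsm,
            "DNN-DSM": dnn,
        }
        variant_sms = {k: v for k, v in variant_sms.items() if k in variants_to_evaluate}
        df = run_evaluation(
            variant_sms,
            projection_sm=data.true_sm,
            positions=test_positions(),
            n_events=config.n_events,
            n_iter=config.n_iter,
            seed=seed_for(config.master_seed, "evaluation"),
        )
        result.eval_records = df
        result.eval_summary = summarize_evaluation(df)
    return result
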