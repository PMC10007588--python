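"""Training loop: mini-batch MSE with Adam and exponential LR decay.

Defaults follow the denoising protocol: batch size 16, MSE loss, Adam with
initial learning rate 1e-4 decayed by a factor 0.996 per epoch, and a fixed
per-(source, group) epoch budget taken from :func:`table_epochs` at full
scale.  Inputs and labels are normalised by a single per-training-set
scalar (the mean label value) so the optimiser sees order-one pixel values
regardless of the count level; the scalar is stored with the model and
inverted at application time, which commutes with the residual connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkSpec, UNet

__all__ = ["TrainConfig", "TrainedDenoiser", "TrainingDiverged", "Adam", "train", "table_epochs"]


# Fixed-epoch budgets per (variant, source label, group) used at full scale.
_EPOCH_TABLE = {
    ("unet", "Tc99m"): (250, 225, 150),
    ("res_unet", "Tc99m"): (250, 200, 135),
    ("unet", "Cs137"): (125, 125, 120),
    ("res_unet", "Cs137"): (120, 125, 130),
}


def table_epochs(variant: str, source: str, group: int) -> int:
    """Full-scale epoch budget for a (network variant, source, group)."""
    try:
        return _EPOCH_TABLE[(variant, source)][group - 1]
    except (KeyError, IndexError):
        raise KeyError(f"no epoch entry for ({variant}, {source}, group {group})") from None


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainConfig:
    batch_size: int = 16
    initial_lr: float = 1e-4
    lr_decay: float = 0.996  # multiplicative, applied per decay_cadence
    decay_cadence: str = "epoch"  # or "step"
    epochs: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.initial_lr <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, initial_lr and batch_size must be positive")
        if self.decay_cadence not in ("epoch", "step"):
            raise ValueError("decay_cadence must be 'epoch' or 'step'")

    def learning_rate(self, epoch: int) -> float:
        """Learning rate in force during ``epoch`` (0-based) for per-epoch decay."""
        return self.initial_lr * self.lr_decay**epoch


class Adam:
    """Adaptive-moment estimation on the network's parameter triples."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p[k]) for p, _, k in params]
        self.v = [np.zeros_like(p[k]) for p, _, k in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g, k) in enumerate(self.params):
            grad = g[k]
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedDenoiser:
    """A trained (or freshly built) denoiser bound to one DRF group."""

    net: UNet
    spec: NetworkSpec
    config: TrainConfig | None = None
    group: int | None = None
    source_label: str | None = None
    loss_history: list = field(default_factory=list)
    input_scale: float = 1.0

    def __call__(self, images: np.ndarray) -> np.ndarray:
        """Denoise a batch of (N, H, W) images; returns the same shape."""
        x = np.asarray(images, dtype=float)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        y = self.net.forward(x[:, None] / self.input_scale)[:, 0] * self.input_scale
        return y[0] if squeeze else y


def build_network(spec: NetworkSpec, seed=None) -> TrainedDenoiser:
    """An untrained denoiser with seeded variance-scaling initialisation."""
    return TrainedDenoiser(net=UNet(spec, seed=seed), spec=spec)


def train(
    inputs: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    spec: NetworkSpec,
    group: int | None = None,
    source_label: str | None = None,
) -> TrainedDenoiser:
    """Fit a denoiser on paired (noisy input, clean label) image stacks.

    ``inputs`` and ``labels`` are (M, H, W) with H, W divisible by 16.
    Batching order is reshuffled each epoch from the config seed; the mean
    loss of every epoch is recorded in the returned model's history.
    """
    x = np.asarray(inputs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape or x.ndim != 3:
        raise ValueError("inputs and labels must be matching (M, H, W) stacks")
    if x.shape[0] == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    scale = float(y.mean())
    if scale <= 0:
        scale = 1.0
    xn = x / scale
    yn = y / scale

    model = build_network(spec, seed=rng.integers(2**31))
    model.config = config
    model.group = group
    model.source_label = source_label
    model.input_scale = scale
    opt = Adam(model.net.parameters())

    m = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(m)
        losses = []
        lr = config.learning_rate(epoch)
        for start in range(0, m, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = xn[idx][:, None]
            yb = yn[idx][:, None]
            pred = model.net.forward(xb)
            diff = pred - yb
            with np.errstate(over="ignore", invalid="ignore"):
                loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size} "
                    f"(group={group}, source={source_label})"
                )
            model.net.zero_grads()
            model.net.backward(2.0 * diff / diff.size)
            if config.decay_cadence == "step":
                lr = config.initial_lr * config.lr_decay**opt.t
            opt.step(lr)
            losses.append(loss)
        model.loss_history.append(float(np.mean(losses)))
    return model
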