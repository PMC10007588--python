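"""The DRF-denoising encoder-decoder architectures.

Both variants share the same U-shaped body: four encoder stacks (two
same-padded 3x3 convolutions + rectifier each, then 2x2 stride-2 max
pooling), a two-convolution bottleneck, four decoder stacks (2x2 stride-2
up-convolution, concatenation with the matching encoder features, two
convolutions + rectifier) and a final 1x1 convolution down to one channel.
Channel width doubles per level from ``base_channels``.  With four
pool/up-conv pairs, input height and width must be divisible by 16; the
output then has the input's spatial shape.

``res_unet`` additionally adds the network input to the output (a global
residual connection): the body then only has to learn the noise correction,
which eases training on count images whose large-scale structure the input
already carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv2D, ConvTranspose2D, MaxPool2D, ReLU

__all__ = ["NetworkSpec", "UNet"]

_VARIANTS = ("unet", "res_unet")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters (defaults match the full-scale model;
    ``base_channels`` is commonly lowered for CPU-scale runs)."""

    variant: str = "res_unet"
    depth: int = 4
    convs_per_stack: int = 2
    kernel: int = 3
    base_channels: int = 64

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be positive")

    @property
    def spatial_divisor(self) -> int:
        return 2**self.depth


class _ConvStack:
    """``convs_per_stack`` same-padded convolutions, each followed by ReLU."""

    def __init__(self, channels: list[int], kernel: int, rng):
        self.layers = []
        for cin, cout in zip(channels[:-1], channels[1:]):
            self.layers.append(Conv2D(cin, cout, kernel, rng))
            self.layers.append(ReLU())

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class UNet:
    """U-shaped denoiser; see module docstring.  Input/output arrays are
    (batch, 1, H, W) with H, W divisible by ``2**depth``."""

    def __init__(self, spec: NetworkSpec, seed=None):
        rng = np.random.default_rng(seed)
        self.spec = spec
        b, d, k, m = spec.base_channels, spec.depth, spec.kernel, spec.convs_per_stack
        enc_ch = [b * 2**i for i in range(d)]  # channels after each encoder stack
        bott_ch = b * 2**d

        self.encoder = []
        cin = 1
        for ch in enc_ch:
            self.encoder.append(_ConvStack([cin] + [ch] * m, k, rng))
            cin = ch
        self.pools = [MaxPool2D() for _ in range(d)]
        self.bottleneck = _ConvStack([enc_ch[-1]] + [bott_ch] * m, k, rng)

        self.upconvs = []
        self.decoder = []
        ch = bott_ch
        for skip_ch in reversed(enc_ch):
            self.upconvs.append(ConvTranspose2D(ch, skip_ch, rng))
            self.decoder.append(_ConvStack([2 * skip_ch] + [skip_ch] * m, k, rng))
            ch = skip_ch
        self.final = Conv2D(ch, 1, 1, rng)
        if spec.variant == "res_unet":
            # zero-init the residual branch: the network starts as the
            # identity map and learns only the noise correction
            self.final.params["W"][...] = 0.0
        self._concat_split = None

    # -- graph execution -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (batch, 1, H, W)")
        div = self.spec.spatial_divisor
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(f"spatial dims must be divisible by {div}, got {x.shape[2:]}")
        skips = []
        h = x
        for stack, pool in zip(self.encoder, self.pools):
            h = stack.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._concat_split = []
        for up, stack, skip in zip(self.upconvs, self.decoder, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=1)
            self._concat_split.append(skip.shape[1])
            h = stack.forward(h)
        y = self.final.forward(h)
        if self.spec.variant == "res_unet":
            y = y + x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dres = dy if self.spec.variant == "res_unet" else 0.0
        d = self.final.backward(dy)
        dskips = []
        for up, stack, ncat in zip(
            reversed(self.upconvs), reversed(self.decoder), reversed(self._concat_split)
        ):
            d = stack.backward(d)
            dskip, d = d[:, :ncat], d[:, ncat:]
            dskips.append(dskip)
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        # dskips were collected shallow-to-deep; encoder unwinds deep-to-shallow
        for stack, pool, dskip in zip(
            reversed(self.encoder), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = d + dskip
            d = stack.backward(d)
        return d + dres

    # -- parameter access ------------------------------------------------
    def _all_layers(self):
        for stack in self.encoder:
            yield from stack.layers
        yield from self.pools
        yield from self.bottleneck.layers
        for up, stack in zip(self.upconvs, self.decoder):
            yield up
            yield from stack.layers
        yield self.final

    def parameters(self):
        """Flat list of (params-dict, grads-dict, key) triples."""
        out = []
        for layer in self._all_layers():
            for key in layer.params:
                out.append((layer.params, layer.grads, key))
        return out

    def zero_grads(self) -> None:
        for layer in self._all_layers():
            for key in layer.grads:
                layer.grads[key][...] = 0.0

    def n_parameters(self) -> int:
        return sum(p[k].size for p, _, k in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p[k] for p, _, k in self.parameters()]
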