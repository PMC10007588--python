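"""MLEM reconstruction of the spherical radioactivity image.

The imaging model is Poisson counting: the expected projection is
``q_j = sum_i a_ij x_i`` for system matrix ``{a_ij}`` and image ``{x_i}``.
The maximum-likelihood expectation-maximisation update is multiplicative,

    x_i <- (x_i / s_i) * sum_j a_ij * p_j / q_j,     s_i = sum_j a_ij,

run plain for a fixed iteration count (default 10,000), with no subsets,
regularisation or stopping rule.  Pixels with zero sensitivity are removed
from the image support; detector bins with zero forward projection and zero
measured counts contribute nothing (the 0/0 ratio is taken as 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .detector import simulate_projection
from .geometry import AngularGrid
from .sm import SystemMatrix

__all__ = ["SkyImage", "mlem", "reconstruct_point"]


@dataclass
class SkyImage:
    """Reconstructed radioactivity v(theta, phi) on an angular grid."""

    values: np.ndarray  # flat, grid pixel order
    grid: AngularGrid
    n_iterations: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_pixels,):
            raise ValueError("values must be flat in grid pixel order")
        if np.any(v < 0):
            raise ValueError("radioactivity must be nonnegative")
        self.values = v

    @property
    def image(self) -> np.ndarray:
        """(n_theta, n_phi) view of the image."""
        return self.values.reshape(self.grid.shape)


def mlem(
    sm: SystemMatrix,
    projection: np.ndarray,
    n_iter: int = 10_000,
    init: np.ndarray | None = None,
) -> SkyImage:
    """Plain MLEM; see module docstring.

    ``init`` must be positive where provided (default: uniform ones).
    Raises if the projection is all zero or negative, or if every pixel has
    zero sensitivity.
    """
    p = np.asarray(projection, dtype=float)
    if p.shape != (sm.n_bins,):
        raise ValueError(f"projection length {p.shape} does not match {sm.n_bins} bins")
    if np.any(p < 0):
        raise ValueError("projection counts must be nonnegative")
    if not np.any(p > 0):
        raise ValueError("projection is all zero")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    a = sm.values
    sens = a.sum(axis=1)
    support = sens > 0
    if not support.any():
        raise ValueError("every pixel has zero sensitivity")
    dead_bins = a.sum(axis=0) <= 0
    if dead_bins.any():
        if np.any(p[dead_bins] > 0):
            warnings.warn(
                f"{int(dead_bins.sum())} detector bin(s) have zero system-matrix "
                "column but nonzero counts; they are excluded from the update",
                stacklevel=2,
            )
        a = a[:, ~dead_bins]
        p = p[~dead_bins]

    asup = a[support]
    ssup = sens[support]
    if init is None:
        x = np.ones(support.sum())
    else:
        init = np.asarray(init, dtype=float)
        if init.shape != (sm.n_pixels,):
            raise ValueError("init must have one value per pixel")
        if np.any(init[support] <= 0):
            raise ValueError("init must be positive on the supported pixels")
        x = init[support].copy()

    for _ in range(n_iter):
        q = x @ asup
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(q > 0, p / np.where(q > 0, q, 1.0), 0.0)
        x = (x / ssup) * (asup @ ratio)

    out = np.zeros(sm.n_pixels)
    out[support] = x
    return SkyImage(out, sm.grid, n_iterations=n_iter, metadata={"sm": dict(sm.metadata)})


def reconstruct_point(
    sm: SystemMatrix,
    theta: float,
    phi: float,
    n_events: int = 1_000_000,
    n_iter: int = 10_000,
    seed=None,
    projection_sm: SystemMatrix | None = None,
) -> SkyImage:
    """Simulate a point-source projection and reconstruct it.

    ``projection_sm`` lets the measurement come from a different (e.g. the
    noiseless true) system matrix than the one used in reconstruction —
    the standard way to evaluate a denoised SM against reality.
    """
    src = projection_sm if projection_sm is not None else sm
    proj = simulate_projection(src, theta, phi, n_events=n_events, seed=seed)
    img = mlem(sm, proj, n_iter=n_iter)
    img.metadata.update({"theta_true": theta, "phi_true": phi, "n_events": n_events})
    return img
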