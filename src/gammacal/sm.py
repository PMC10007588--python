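"""System-matrix container, DRF decomposition, interpolation and scaling.

The system matrix ``{a_ij}`` links image pixel ``i`` (a direction on the
angular grid) to detector bin ``j``.  Each column, reshaped onto the grid,
is the detector response function (DRF) of one bin: a 2D image over
(phi, theta) of that bin's detection probability.  Denoising operates on
DRF images; a denoised system matrix is re-assembled from denoised DRFs.

Normative layouts
-----------------
* SM rows are in the grid's row-major (theta outer, phi inner) pixel order.
* DRF images are (phi rows, theta columns) — e.g. 360 x 91 on the 1-degree
  hemisphere grid.
* On-disk container: HDF5 with datasets ``values``, ``theta``, ``phi`` and
  a JSON metadata attribute; ``.npz`` with the same keys as fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RectBivariateSpline

from .geometry import AngularGrid, make_fine_grid

__all__ = [
    "SystemMatrix",
    "DRFImage",
    "PaddedDRF",
    "ScalingFactors",
    "extract_drf",
    "assemble_sm",
    "interpolate_coarse_to_fine",
    "pad_image",
    "crop_image",
    "pad_drf",
    "crop_drf",
    "compute_scaling",
    "apply_scaling",
    "invert_scaling",
    "save_sm",
    "load_sm",
]


@dataclass
class SystemMatrix:
    """Nonnegative (n_pixels, n_bins) array tied to an angular grid."""

    values: np.ndarray
    grid: AngularGrid
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("system matrix must be 2-D (pixels x bins)")
        if vals.shape[0] != self.grid.n_pixels:
            raise ValueError(
                f"row count {vals.shape[0]} does not match grid pixels {self.grid.n_pixels}"
            )
        if np.any(vals < 0):
            raise ValueError("system matrix entries must be nonnegative")
        self.values = vals

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def bin_totals(self) -> np.ndarray:
        """Total counts per detector bin (the bin's sensitivity)."""
        return self.values.sum(axis=0)

    def scaled(self, factor: float) -> "SystemMatrix":
        return SystemMatrix(self.values * factor, self.grid, dict(self.metadata))


@dataclass
class DRFImage:
    """One detector bin's response as a (phi, theta) image."""

    image: np.ndarray
    bin_index: int

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValueError("DRF image must be 2-D")
        if np.any(img < 0):
            raise ValueError("DRF image must be nonnegative")
        self.image = img

    @property
    def total_counts(self) -> float:
        return float(self.image.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class PaddedDRF:
    """A DRF image zero-padded to network-friendly dimensions."""

    image: np.ndarray
    original_shape: tuple[int, int]
    offset: tuple[int, int]
    bin_index: int


@dataclass
class ScalingFactors:
    """Per-bin count-ratio factors F_j between two devices."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or np.any(v <= 0):
            raise ValueError("scaling factors must be a 1-D positive array")
        self.values = v


def extract_drf(sm: SystemMatrix, j: int) -> DRFImage:
    """Column ``j`` of the system matrix as a (phi, theta) image."""
    if not (0 <= j < sm.n_bins):
        raise IndexError(f"bin index {j} out of range [0, {sm.n_bins})")
    col = sm.values[:, j].reshape(sm.grid.n_theta, sm.grid.n_phi)
    return DRFImage(col.T.copy(), bin_index=j)


def assemble_sm(drfs: list[DRFImage], grid: AngularGrid, metadata: dict | None = None) -> SystemMatrix:
    """Inverse of :func:`extract_drf`: stack DRFs back into a system matrix.

    Requires exactly one DRF per bin index 0..n-1 (any order).
    """
    indices = sorted(d.bin_index for d in drfs)
    if indices != list(range(len(drfs))):
        raise ValueError("need exactly one DRF per bin index 0..n-1")
    n_bins = len(drfs)
    values = np.empty((grid.n_pixels, n_bins))
    for d in drfs:
        if d.image.shape != (grid.n_phi, grid.n_theta):
            raise ValueError(
                f"DRF {d.bin_index} shape {d.image.shape} does not match grid "
                f"({grid.n_phi}, {grid.n_theta})"
            )
        values[:, d.bin_index] = d.image.T.ravel()
    return SystemMatrix(values, grid, metadata=dict(metadata or {}))


def interpolate_coarse_to_fine(
    coarse_sm: SystemMatrix, fine_grid: AngularGrid | None = None
) -> SystemMatrix:
    """Per-bin bicubic spline interpolation of a coarse calibration SM.

    phi is periodically extended before fitting (the azimuth is circular);
    theta uses the spline's natural end conditions at the physical edges of
    the hemispherical field of view.  Negative spline overshoot is clipped
    to zero.
    """
    if fine_grid is None:
        fine_grid = make_fine_grid()
    grid = coarse_sm.grid
    if grid.n_theta < 4 or grid.n_phi < 4:
        raise ValueError("coarse grid too small for bicubic interpolation")
    th, ph = grid.theta_values, grid.phi_values
    k = 3
    # periodic extension in phi by k columns on each side
    ph_ext = np.concatenate([ph[-k:] - 360.0, ph, ph[:k] + 360.0])
    fine_th = fine_grid.theta_values
    fine_ph = fine_grid.phi_values
    out = np.empty((fine_grid.n_pixels, coarse_sm.n_bins))
    for j in range(coarse_sm.n_bins):
        img = coarse_sm.values[:, j].reshape(grid.n_theta, grid.n_phi)
        img_ext = np.concatenate([img[:, -k:], img, img[:, :k]], axis=1)
        spline = RectBivariateSpline(th, ph_ext, img_ext, kx=k, ky=k)
        fine = spline(fine_th, fine_ph)
        out[:, j] = np.clip(fine, 0.0, None).ravel()
    meta = dict(coarse_sm.metadata, interpolated_from=f"{grid.n_theta}x{grid.n_phi}")
    return SystemMatrix(out, fine_grid, metadata=meta)


def _padded_dims(shape: tuple[int, int]) -> tuple[int, int]:
    return tuple(16 * int(np.ceil(s / 16)) for s in shape)  # type: ignore[return-value]


def pad_image(image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Zero-pad a 2-D image up to the next multiples of 16 per axis
    (360 x 91 -> 368 x 96), content centred; returns (padded, offset)."""
    h, w = image.shape
    ph, pw = _padded_dims((h, w))
    off = ((ph - h) // 2, (pw - w) // 2)
    out = np.zeros((ph, pw), dtype=image.dtype)
    out[off[0] : off[0] + h, off[1] : off[1] + w] = image
    return out, off


def crop_image(padded: np.ndarray, original_shape: tuple[int, int], offset: tuple[int, int]) -> np.ndarray:
    h, w = original_shape
    return padded[offset[0] : offset[0] + h, offset[1] : offset[1] + w]


def pad_drf(drf: DRFImage) -> PaddedDRF:
    """Pad a DRF image for the denoising networks (dimensions must be
    divisible by 16 to survive four pooling/up-convolution pairs)."""
    padded, off = pad_image(drf.image)
    return PaddedDRF(padded, drf.shape, off, drf.bin_index)


def crop_drf(padded: PaddedDRF) -> DRFImage:
    """Exact inverse of :func:`pad_drf`."""
    img = crop_image(padded.image, padded.original_shape, padded.offset)
    return DRFImage(np.ascontiguousarray(img), padded.bin_index)


def compute_scaling(sm_dev1: SystemMatrix, sm_dev2: SystemMatrix) -> ScalingFactors:
    """Per-bin count ratios F_j = (device-1 DRF total) / (device-2 DRF total).

    Multiplying device-2 DRFs by F_j matches their count level to the
    device the denoising networks were trained on.
    """
    if sm_dev1.values.shape != sm_dev2.values.shape:
        raise ValueError("system matrices must have identical shapes")
    t1 = sm_dev1.bin_totals()
    t2 = sm_dev2.bin_totals()
    zero = np.flatnonzero(t2 <= 0)
    if zero.size:
        raise ValueError(f"device-2 DRF total is zero for bin(s) {zero[:5].tolist()}")
    return ScalingFactors(t1 / t2)


def apply_scaling(sm: SystemMatrix, factors: ScalingFactors) -> SystemMatrix:
    if factors.values.size != sm.n_bins:
        raise ValueError("factor length does not match bin count")
    return SystemMatrix(sm.values * factors.values[None, :], sm.grid, dict(sm.metadata))


def invert_scaling(sm: SystemMatrix, factors: ScalingFactors) -> SystemMatrix:
    if factors.values.size != sm.n_bins:
        raise ValueError("factor length does not match bin count")
    return SystemMatrix(sm.values / factors.values[None, :], sm.grid, dict(sm.metadata))


def save_sm(sm: SystemMatrix, path) -> None:
    """Write a system matrix to ``.h5``/``.hdf5`` (default) or ``.npz``."""
    path = Path(path)
    meta = json.dumps(sm.metadata)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            values=sm.values,
            theta=sm.grid.theta_values,
            phi=sm.grid.phi_values,
            metadata=np.bytes_(meta.encode()),
        )
        return
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=sm.values)
        f.create_dataset("theta", data=sm.grid.theta_values)
        f.create_dataset("phi", data=sm.grid.phi_values)
        f.attrs["metadata"] = meta


def load_sm(path) -> SystemMatrix:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            grid = AngularGrid(f["theta"], f["phi"])
            meta = json.loads(bytes(f["metadata"]).decode())
            return SystemMatrix(f["values"], grid, metadata=meta)
    import h5py

    with h5py.File(path, "r") as f:
        grid = AngularGrid(f["theta"][:], f["phi"][:])
        meta = json.loads(f.attrs["metadata"])
        return SystemMatrix(f["values"][:], grid, metadata=meta)
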