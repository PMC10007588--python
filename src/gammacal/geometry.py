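"""Angular grids and direction arithmetic on the imaging sphere.

The imager reconstructs radioactivity on a sphere centred on the detector
block, parameterised by the polar angle ``theta`` (measured from the
detector's top-view axis) and the azimuth ``phi`` (counter-clockwise from a
fixed reference axis).  All angles in this package are degrees; radians
appear only inside trigonometric calls.

The default field of view is the upper hemisphere (``theta`` in [0, 90]),
matching a ceiling-mounted, top-view deployment; a full-sphere grid is
constructible but not exercised by the calibration pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngularGrid",
    "make_coarse_grid",
    "make_fine_grid",
    "direction_vector",
    "angular_separation",
]


@dataclass(frozen=True)
class AngularGrid:
    """A rectangular (theta, phi) grid on the sphere.

    Pixel order is row-major with theta as the outer axis and phi as the
    inner axis; this ordering is normative across the package (system-matrix
    rows, reconstructed images, DRF extraction all rely on it).
    """

    theta_values: np.ndarray
    phi_values: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta_values, dtype=float)
        phi = np.asarray(self.phi_values, dtype=float)
        if theta.ndim != 1 or phi.ndim != 1:
            raise ValueError("theta_values and phi_values must be 1-D")
        if np.any(np.diff(theta) <= 0) or np.any(np.diff(phi) <= 0):
            raise ValueError("grid angles must be strictly increasing")
        if theta[0] < 0 or theta[-1] > 180:
            raise ValueError("theta must lie in [0, 180]")
        if phi[0] < 0 or phi[-1] >= 360:
            raise ValueError("phi must lie in [0, 360)")
        object.__setattr__(self, "theta_values", theta)
        object.__setattr__(self, "phi_values", phi)

    @property
    def n_theta(self) -> int:
        return self.theta_values.size

    @property
    def n_phi(self) -> int:
        return self.phi_values.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_theta, self.n_phi)

    @property
    def n_pixels(self) -> int:
        return self.n_theta * self.n_phi

    def pixel_index(self, i_theta: int, i_phi: int) -> int:
        """Flat pixel index of grid node (i_theta, i_phi)."""
        if not (0 <= i_theta < self.n_theta and 0 <= i_phi < self.n_phi):
            raise IndexError("grid node out of range")
        return i_theta * self.n_phi + i_phi

    def pixel_angles(self, index: int) -> tuple[float, float]:
        """(theta, phi) in degrees of the flat pixel ``index``."""
        if not (0 <= index < self.n_pixels):
            raise IndexError("pixel index out of range")
        i_theta, i_phi = divmod(index, self.n_phi)
        return float(self.theta_values[i_theta]), float(self.phi_values[i_phi])

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(theta, phi) meshgrids of shape ``self.shape``."""
        return np.meshgrid(self.theta_values, self.phi_values, indexing="ij")

    def directions(self) -> np.ndarray:
        """Unit direction vectors for all pixels, shape (n_pixels, 3)."""
        th, ph = self.mesh()
        return _angles_to_unit(th.ravel(), ph.ravel())


def make_coarse_grid() -> AngularGrid:
    """Calibration measurement grid: theta 0..90 deg and phi 0..350 deg in
    10 deg steps (10 x 36 = 360 source positions over the hemisphere)."""
    return AngularGrid(np.arange(0.0, 91.0, 10.0), np.arange(0.0, 351.0, 10.0))


def make_fine_grid() -> AngularGrid:
    """Reconstruction grid at 1 deg x 1 deg: 91 (theta) x 360 (phi) =
    32,760 pixels over the hemisphere."""
    return AngularGrid(np.arange(0.0, 91.0, 1.0), np.arange(0.0, 360.0, 1.0))


def _angles_to_unit(theta_deg, phi_deg) -> np.ndarray:
    t = np.deg2rad(np.asarray(theta_deg, dtype=float))
    p = np.deg2rad(np.asarray(phi_deg, dtype=float))
    st = np.sin(t)
    out = np.stack([st * np.cos(p), st * np.sin(p), np.cos(t)], axis=-1)
    return out


def direction_vector(theta: float, phi: float) -> np.ndarray:
    """Unit 3-vector for source direction (theta, phi) in degrees.

    theta = 0 maps to the polar (top-view) axis regardless of phi.
    """
    if not (0.0 <= theta <= 180.0):
        raise ValueError(f"theta must be in [0, 180], got {theta}")
    if not (0.0 <= phi < 360.0):
        raise ValueError(f"phi must be in [0, 360), got {phi}")
    return _angles_to_unit(theta, phi)


def angular_separation(a: np.ndarray, b: np.ndarray) -> float:
    """Great-circle angle in degrees between two unit direction vectors.

    The dot product is clamped to [-1, 1] so antipodal/identical pairs do
    not trip on rounding.
    """
    dot = float(np.clip(np.dot(np.asarray(a, float), np.asarray(b, float)), -1.0, 1.0))
    return float(np.rad2deg(np.arccos(dot)))
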