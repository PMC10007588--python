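"""Attenuation-based forward model of the 3D position-sensitive detector.

This is the package's synthetic-data generator.  The physical device is a
monolithic block of ``n_transverse x n_transverse`` scintillator bars read
out in depth layers; a photon arriving from direction ``d`` is detected in a
given bin with probability

    exp(-mu * L_up) * (1 - exp(-mu * L_self)) * edge_factor * jitter

where ``L_up`` is the path length through upstream scintillator (other bins
on the ray, which attenuate the beam), ``L_self`` the chord through the bin
itself, ``mu`` the linear attenuation coefficient at the source energy,
``edge_factor`` a phenomenological penalty on sub-block-edge bins (emulating
energy-window rejection of events split across read-out sub-blocks), and
``jitter`` a per-bin efficiency fingerprint distinguishing physical devices.

The source is far (~0.9 m) compared with the block (~70 mm), so rays are
parallel per direction.  No Compton transport is modelled: the direction
dependence created by self-attenuation is the feature the calibration
pipeline needs, not the full physics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import AngularGrid

__all__ = [
    "DetectorGeometry",
    "SourceSpec",
    "upstream_path_length",
    "chord_lengths",
    "detection_probability",
    "simulate_true_sm",
    "sample_counts",
    "thin_counts",
    "simulate_projection",
    "make_device",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Geometry and per-bin efficiency model of one imager.

    Bins are indexed ``j = (ix * n_transverse + iy) * n_depth_bins + iz``
    with ``iz = 0`` the top (source-facing at theta=0) depth layer.
    """

    n_transverse: int = 16
    crystal_pitch: float = 4.05  # mm
    crystal_depth: float = 20.0  # mm
    n_depth_bins: int = 5
    sub_block_size: int = 8
    mu: float = 0.19  # 1/mm, user-supplied from attenuation tables
    edge_loss: float = 1.0  # multiplicative penalty on sub-block-edge bins
    bin_efficiency_jitter: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_transverse % self.sub_block_size != 0:
            raise ValueError("n_transverse must be divisible by sub_block_size")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if not (0.0 <= self.edge_loss <= 1.0):
            raise ValueError("edge_loss must be in [0, 1]")
        if self.bin_efficiency_jitter is not None:
            jit = np.asarray(self.bin_efficiency_jitter, dtype=float)
            if jit.shape != (self.n_bins,):
                raise ValueError(f"jitter must have shape ({self.n_bins},)")
            if np.any(jit <= 0):
                raise ValueError("jitter factors must be positive")
            object.__setattr__(self, "bin_efficiency_jitter", jit)

    @property
    def n_bins(self) -> int:
        return self.n_transverse * self.n_transverse * self.n_depth_bins

    @property
    def depth_bin_thickness(self) -> float:
        return self.crystal_depth / self.n_depth_bins

    @property
    def block_half_width(self) -> float:
        return 0.5 * self.n_transverse * self.crystal_pitch

    def bin_index(self, ix: int, iy: int, iz: int) -> int:
        n, nz = self.n_transverse, self.n_depth_bins
        if not (0 <= ix < n and 0 <= iy < n and 0 <= iz < nz):
            raise IndexError("bin coordinates out of range")
        return (ix * n + iy) * nz + iz

    def bin_coords(self, j: int) -> tuple[int, int, int]:
        n, nz = self.n_transverse, self.n_depth_bins
        if not (0 <= j < self.n_bins):
            raise IndexError("bin index out of range")
        ixy, iz = divmod(j, nz)
        ix, iy = divmod(ixy, n)
        return ix, iy, iz

    def bin_centers(self) -> np.ndarray:
        """Centres of all bins, shape (n_bins, 3), mm, block centred at 0.

        z increases toward the source at theta=0; layer iz=0 is topmost.
        """
        n, nz = self.n_transverse, self.n_depth_bins
        pitch, dz = self.crystal_pitch, self.depth_bin_thickness
        tx = (np.arange(n) + 0.5) * pitch - self.block_half_width
        zc = 0.5 * self.crystal_depth - (np.arange(nz) + 0.5) * dz
        ix, iy, iz = np.meshgrid(np.arange(n), np.arange(n), np.arange(nz), indexing="ij")
        centers = np.stack(
            [tx[ix.ravel()], tx[iy.ravel()], zc[iz.ravel()]], axis=-1
        )
        return centers

    def bin_half_sizes(self) -> np.ndarray:
        """Half-extents (hx, hy, hz) of every bin box, shape (n_bins, 3)."""
        h = np.array(
            [0.5 * self.crystal_pitch, 0.5 * self.crystal_pitch, 0.5 * self.depth_bin_thickness]
        )
        return np.broadcast_to(h, (self.n_bins, 3))

    def edge_mask(self) -> np.ndarray:
        """Boolean mask of bins lying on an internal sub-block edge.

        These are the bins whose transverse row or column abuts the boundary
        between read-out sub-blocks (the "cross" pattern); the outer faces
        of the block do not count.
        """
        n, s = self.n_transverse, self.sub_block_size
        idx = np.arange(n)
        on_edge_1d = ((idx % s == 0) | (idx % s == s - 1)) & (idx != 0) & (idx != n - 1)
        ix, iy, _ = np.meshgrid(
            np.arange(n), np.arange(n), np.arange(self.n_depth_bins), indexing="ij"
        )
        mask = on_edge_1d[ix.ravel()] | on_edge_1d[iy.ravel()]
        return mask

    def edge_factors(self) -> np.ndarray:
        f = np.ones(self.n_bins)
        f[self.edge_mask()] = self.edge_loss
        return f

    def jitter_factors(self) -> np.ndarray:
        if self.bin_efficiency_jitter is None:
            return np.ones(self.n_bins)
        return self.bin_efficiency_jitter


@dataclass(frozen=True)
class SourceSpec:
    """A calibration source: label, attenuation coefficient at its energy,
    and the expected number of detected events per calibration grid point
    at the full acquisition time."""

    label: str = "Tc99m"
    mu: float = 0.19  # 1/mm in the scintillator at this energy
    events_per_point: float = 1.0e7

    def __post_init__(self) -> None:
        if self.events_per_point <= 0:
            raise ValueError("events_per_point must be positive")
        if self.mu <= 0:
            raise ValueError("mu must be positive")


def _ray_intervals(
    lo_bound: np.ndarray, hi_bound: np.ndarray, direction: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Slab-method entry/exit parameters of rays p(t) = origin + t*direction
    through axis-aligned boxes whose face coordinates ``lo_bound``/
    ``hi_bound`` (shape (n, 3)) are given RELATIVE to each ray's origin.
    Axes with zero direction component are treated as always inside, which
    is valid here because every ray origin lies inside its box's slabs."""
    d = np.asarray(direction, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_a = lo_bound / d
        t_b = hi_bound / d
    lo = np.minimum(t_a, t_b)
    hi = np.maximum(t_a, t_b)
    lo = np.where(np.isfinite(lo), lo, -np.inf)
    hi = np.where(np.isfinite(hi), hi, np.inf)
    return lo.max(axis=1), hi.min(axis=1)


def _path_lengths(geometry: DetectorGeometry, direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(L_up, L_self) in mm for every bin for one source direction.

    The ray for bin j runs through the bin centre toward the source
    (parallel-beam, far-field).  L_self is the chord through the bin box;
    L_up is the remaining in-block path on the source side of the bin.
    """
    d = np.asarray(direction, float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    centers = geometry.bin_centers()
    half = geometry.bin_half_sizes()
    t0_bin, t1_bin = _ray_intervals(-half, half, d)
    w = geometry.block_half_width
    block_half = np.array([w, w, 0.5 * geometry.crystal_depth])
    t0_blk, t1_blk = _ray_intervals(-block_half - centers, block_half - centers, d)
    l_self = t1_bin - t0_bin
    l_up = np.maximum(t1_blk - t1_bin, 0.0)
    return l_up, l_self


def upstream_path_length(geometry: DetectorGeometry, bin_index: int, direction: np.ndarray) -> float:
    """Scintillator path length (mm) upstream of ``bin_index`` along the ray
    from the source direction ``direction`` (unit vector)."""
    l_up, _ = _path_lengths(geometry, direction)
    return float(l_up[bin_index])


def chord_lengths(geometry: DetectorGeometry, bin_index: int, direction: np.ndarray) -> tuple[float, float]:
    """(upstream length, self chord) in mm for one bin and direction."""
    l_up, l_self = _path_lengths(geometry, direction)
    return float(l_up[bin_index]), float(l_self[bin_index])


def detection_probability(
    geometry: DetectorGeometry, bin_index: int | None, direction: np.ndarray, mu: float | None = None
) -> float | np.ndarray:
    """Detection probability of a photon from ``direction``.

    With ``bin_index=None`` returns the full vector over bins.  ``mu``
    defaults to the geometry's coefficient; pass the source's value to
    evaluate another energy.
    """
    mu = geometry.mu if mu is None else mu
    l_up, l_self = _path_lengths(geometry, direction)
    p = np.exp(-mu * l_up) * (1.0 - np.exp(-mu * l_self))
    p = p * geometry.edge_factors() * geometry.jitter_factors()
    if bin_index is None:
        return p
    return float(p[bin_index])


def simulate_true_sm(geometry: DetectorGeometry, source: SourceSpec, grid: AngularGrid):
    """Noiseless expected system matrix on ``grid``.

    Row i holds the per-bin detection probabilities for source direction i,
    scaled so every row totals ``source.events_per_point`` (the calibration
    protocol acquires a fixed source exposure at each grid point).
    Deterministic given the geometry.
    """
    from .sm import SystemMatrix

    dirs = grid.directions()
    values = np.empty((grid.n_pixels, geometry.n_bins))
    for i, d in enumerate(dirs):
        p = detection_probability(geometry, None, d, mu=source.mu)
        total = p.sum()
        if total <= 0:
            raise ValueError(f"direction {i} yields zero total sensitivity")
        values[i] = p * (source.events_per_point / total)
    return SystemMatrix(values, grid, metadata={"source": source.label, "kind": "true"})


def sample_counts(sm_expected, seed):
    """Poisson realisation of an expected-count system matrix."""
    from .sm import SystemMatrix

    rng = np.random.default_rng(seed)
    counts = rng.poisson(sm_expected.values).astype(np.int64)
    meta = dict(sm_expected.metadata, kind="counts", seed=_seed_repr(seed))
    return SystemMatrix(counts, sm_expected.grid, metadata=meta)


def thin_counts(sm_counts, fraction: float, seed):
    """Binomial thinning of an integer-count system matrix.

    Keeping each recorded event independently with probability ``fraction``
    is exactly equivalent to uniform subsampling of the list-mode event
    stream, so a 10% thinning emulates a 10% acquisition time.
    """
    from .sm import SystemMatrix

    vals = sm_counts.values
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("thin_counts requires integer counts")
        vals = np.round(vals).astype(np.int64)
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(vals, fraction)
    meta = dict(sm_counts.metadata, kind="thinned", fraction=fraction, seed=_seed_repr(seed))
    return SystemMatrix(thinned.astype(np.int64), sm_counts.grid, metadata=meta)


def simulate_projection(sm, theta: float, phi: float, n_events: int = 1_000_000, seed=None) -> np.ndarray:
    """Multinomial projection of ``n_events`` photons from (theta, phi).

    Off-node positions use bilinear interpolation between the four
    surrounding grid rows (periodic in phi).  The returned integer vector
    sums to ``n_events`` exactly.
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    row = interpolate_sm_row(sm, theta, phi)
    total = row.sum()
    if total <= 0:
        raise ValueError("interpolated system-matrix row is all zero")
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(n_events), row / total)


def interpolate_sm_row(sm, theta: float, phi: float) -> np.ndarray:
    """Bilinearly interpolated system-matrix row at (theta, phi) degrees."""
    grid = sm.grid
    th, ph = grid.theta_values, grid.phi_values
    if not (th[0] <= theta <= th[-1]):
        raise ValueError(f"theta={theta} outside grid range [{th[0]}, {th[-1]}]")
    it = int(np.clip(np.searchsorted(th, theta) - 1, 0, th.size - 2))
    wt = (theta - th[it]) / (th[it + 1] - th[it])
    # periodic phi: wrap into [phi0, phi0+360)
    period = 360.0
    p = (phi - ph[0]) % period + ph[0]
    ip = int(np.searchsorted(ph, p) - 1)
    if ip < 0:
        ip = ph.size - 1
    ip_next = (ip + 1) % ph.size
    span = (ph[ip_next] - ph[ip]) % period
    if span == 0:
        wp = 0.0
    else:
        wp = ((p - ph[ip]) % period) / span
    vals = sm.values
    npix_phi = grid.n_phi

    def row_at(i_t, i_p):
        return vals[i_t * npix_phi + i_p]

    row = (
        (1 - wt) * (1 - wp) * row_at(it, ip)
        + (1 - wt) * wp * row_at(it, ip_next)
        + wt * (1 - wp) * row_at(it + 1, ip)
        + wt * wp * row_at(it + 1, ip_next)
    )
    return np.asarray(row, dtype=float)


def make_device(geometry: DetectorGeometry, device_seed, jitter_spread: float = 0.2) -> DetectorGeometry:
    """A second physical device: same geometry, independent per-bin
    efficiency fingerprint drawn log-normally (median 1, log-sd
    ``jitter_spread``).  Spread 0 returns the reference device unchanged."""
    if jitter_spread < 0:
        raise ValueError("jitter_spread must be >= 0")
    if jitter_spread == 0:
        return replace(geometry, bin_efficiency_jitter=None)
    rng = np.random.default_rng(device_seed)
    jit = np.exp(rng.normal(0.0, jitter_spread, size=geometry.n_bins))
    return replace(geometry, bin_efficiency_jitter=jit)


def _seed_repr(seed) -> str:
    try:
        return str(int(seed))
    except (TypeError, ValueError):
        return repr(seed)
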