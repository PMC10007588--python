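"""Sensitivity maps and self-adaptive K-means grouping of DRFs.

Detector bins differ strongly in sensitivity (total DRF counts): surface
layers shield deep layers, sub-block-edge bins lose split events to the
energy window, and read-out chains differ bin to bin.  Because the optimal
denoising network depends on the count level of its inputs, DRFs are
clustered by sensitivity into ``k`` groups (default 3) and one network is
trained per group.  Clustering is one-dimensional K-means on the raw
sensitivities with Euclidean distance; groups are relabelled so group 1 has
the highest mean sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .detector import DetectorGeometry
from .sm import SystemMatrix

__all__ = ["GroupAssignment", "sensitivity_map", "kmeans_group"]


@dataclass
class GroupAssignment:
    """Group labels (1..k) per detector bin, ordered by descending centroid."""

    labels: np.ndarray
    centroids: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.size != self.k:
            raise ValueError("need one centroid per group")
        if np.any(np.diff(self.centroids) >= 0):
            raise ValueError("centroids must be strictly decreasing (group 1 = most sensitive)")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError("every group 1..k must be non-empty")

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]

    def members(self, group: int) -> np.ndarray:
        """Bin indices belonging to ``group`` (1-based)."""
        if not (1 <= group <= self.k):
            raise IndexError(f"group {group} out of range 1..{self.k}")
        return np.flatnonzero(self.labels == group)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "labels": self.labels.tolist(),
            "centroids": self.centroids.tolist(),
            "group_sizes": self.group_sizes.tolist(),
        }


def sensitivity_map(sm: SystemMatrix, geometry: DetectorGeometry | None = None) -> np.ndarray:
    """Per-bin total counts; with a geometry, arranged on the
    (transverse x, transverse y, depth layer) lattice."""
    totals = sm.bin_totals()
    if geometry is None:
        return totals
    if totals.size != geometry.n_bins:
        raise ValueError("system matrix bin count does not match geometry")
    n, nz = geometry.n_transverse, geometry.n_depth_bins
    return totals.reshape(n, n, nz)


def kmeans_group(
    sensitivities: np.ndarray,
    k: int = 3,
    seed=None,
    n_init: int = 10,
    init: str = "k-means++",
) -> GroupAssignment:
    """Cluster per-bin sensitivities into ``k`` groups with 1-D K-means.

    Lloyd iterations run to convergence from ``n_init`` seeded k-means++
    starts (``init="random"`` reproduces plain random-item initialisation);
    the best-inertia solution is kept, so the grouping is deterministic for
    a fixed seed.  Labels are renumbered in order of descending centroid.
    """
    x = np.asarray(sensitivities, dtype=float).ravel()
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct sensitivity values")
    km = KMeans(n_clusters=k, init=init, n_init=n_init, random_state=_to_int_seed(seed))
    raw = km.fit_predict(x[:, None])
    centroids = km.cluster_centers_.ravel()
    order = np.argsort(-centroids)  # group 1 = highest sensitivity
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return GroupAssignment(labels=relabel[raw], centroids=centroids[order], k=k)


def _to_int_seed(seed) -> int | None:
    if seed is None:
        return None
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
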