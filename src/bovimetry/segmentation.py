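"""Euclidean cluster extraction and RANSAC planar ground removal.

After filtering, the subject and the floor it stands on form one connected
blob while walls and clutter sit in separate blobs.  Segmentation therefore
(1) partitions the cloud into Euclidean-connectivity clusters and takes the
largest as the target, then (2) fits the dominant plane in that cluster with
RANSAC and strips its inliers — the floor — leaving the animal.  The fitted
plane doubles as the height datum for all later body measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core_io import PointCloud

logger = logging.getLogger("bovimetry")

__all__ = [
    "ClusterParams",
    "RansacParams",
    "PlaneModel",
    "euclidean_cluster_extract",
    "ransac_plane",
    "segment_target",
]


@dataclass
class ClusterParams:
    tolerance: float = 0.05          # neighbour-link radius, metres
    min_cluster_size: int = 50
    max_cluster_size: int | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_cluster_size is not None and self.min_cluster_size > self.max_cluster_size:
            raise ValueError("min_cluster_size > max_cluster_size")


@dataclass
class RansacParams:
    distance_threshold: float = 0.02  # inlier point-plane distance, metres
    max_iterations: int = 1000
    seed: int | None = None
    early_exit_inlier_ratio: float = 0.9

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class PlaneModel:
    """Plane {p : normal·p + offset = 0} with its supporting inliers."""

    normal: np.ndarray
    offset: float
    inlier_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal must be nonzero")
        self.normal = n / norm
        self.offset = float(self.offset) / norm

    def distance(self, pts: np.ndarray) -> np.ndarray:
        """Unsigned perpendicular distance of points to the plane."""
        return np.abs(np.atleast_2d(pts) @ self.normal + self.offset)

    def project(self, pts: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        p = np.atleast_2d(pts)
        signed = p @ self.normal + self.offset
        return p - signed[:, None] * self.normal


def euclidean_cluster_extract(
    cloud: PointCloud, params: ClusterParams | None = None
) -> list[PointCloud]:
    """Connected components of the graph linking points within ``tolerance``.

    Clusters smaller than ``min_cluster_size`` (or larger than
    ``max_cluster_size``) are discarded; survivors are returned sorted by size,
    largest first.
    """
    params = params or ClusterParams()
    n = len(cloud)
    if n == 0:
        raise ValueError("cannot cluster an empty cloud")
    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(params.tolerance, output_type="ndarray")
    if len(pairs):
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if len(idx) < params.min_cluster_size:
            continue
        if params.max_cluster_size is not None and len(idx) > params.max_cluster_size:
            continue
        clusters.append(cloud.select(idx))
    clusters.sort(key=len, reverse=True)
    if not clusters:
        logger.warning("no cluster met min_cluster_size=%d", params.min_cluster_size)
    return clusters


def ransac_plane(cloud: PointCloud, params: RansacParams | None = None) -> PlaneModel:
    """Robust plane fit: best 3-point hypothesis by inlier count, then refit.

    The winning consensus set is refit by total least squares (smallest
    eigenvector of the inlier covariance).  Deterministic under a fixed seed.
    """
    params = params or RansacParams()
    pts = cloud.points
    n = len(pts)
    if n < 3:
        raise ValueError("plane fitting needs at least 3 points")
    rng = np.random.default_rng(params.seed)
    best_count, best_inliers = -1, None
    for _ in range(params.max_iterations):
        i, j, k = rng.choice(n, size=3, replace=False)
        v1, v2 = pts[j] - pts[i], pts[k] - pts[i]
        normal = np.cross(v1, v2)
        nn = np.linalg.norm(normal)
        if nn < 1e-12:          # collinear sample, try again
            continue
        normal = normal / nn
        offset = -normal @ pts[i]
        dist = np.abs(pts @ normal + offset)
        inliers = dist <= params.distance_threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count, best_inliers = count, inliers
            if count >= params.early_exit_inlier_ratio * n:
                break
    if best_inliers is None:
        raise ValueError("degenerate input: all RANSAC samples were collinear")
    # least-squares refit on the consensus set
    idx = np.flatnonzero(best_inliers)
    sub = pts[idx]
    centroid = sub.mean(axis=0)
    cov = np.cov((sub - centroid).T)
    eigval, eigvec = np.linalg.eigh(cov)
    normal = eigvec[:, 0]
    offset = -normal @ centroid
    # recompute inliers under the refined model
    dist = np.abs(pts @ normal + offset)
    idx = np.flatnonzero(dist <= params.distance_threshold)
    return PlaneModel(normal, offset, idx)


def segment_target(
    cloud: PointCloud,
    cluster_params: ClusterParams | None = None,
    ransac_params: RansacParams | None = None,
) -> tuple[PointCloud, PlaneModel]:
    """Largest cluster minus its RANSAC ground plane.

    Returns the remaining (subject) cloud and the fitted :class:`PlaneModel`,
    which downstream measurement uses as the height datum.
    """
    cluster_params = cluster_params or ClusterParams()
    clusters = euclidean_cluster_extract(cloud, cluster_params)
    if not clusters:
        raise ValueError(
            f"largest cluster below min_cluster_size={cluster_params.min_cluster_size}"
        )
    target = clusters[0]
    plane = ransac_plane(target, ransac_params)
    keep = np.setdiff1d(np.arange(len(target)), plane.inlier_indices)
    logger.info(
        "segment_target: cluster %d pts, plane removed %d, body %d",
        len(target), len(plane.inlier_indices), len(keep),
    )
    return target.select(keep), plane
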