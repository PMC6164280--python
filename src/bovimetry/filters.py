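"""Three-filter fusion preprocessing: pass-band, statistical outlier, voxel grid.

A raw time-of-flight frame mixes the animal with background walls, sparse
flying-pixel outliers and far more points than downstream stages need.  The
fused preprocessing chain removes each in turn:

1. conditional (pass-band) removal — keep only points inside an open x/z box
   around the subject (the vertical axis is unconstrained);
2. statistical outlier removal — score each point by its mean distance to its
   ``mean_k`` nearest neighbours and drop points whose score exceeds
   mean + ``stddev_mult``·std of all scores;
3. voxel-grid downsampling — replace all points in each occupied cube of edge
   ``leaf_size`` by their centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core_io import PointCloud

logger = logging.getLogger("bovimetry")

__all__ = [
    "FilterParams",
    "conditional_filter",
    "statistical_outlier_filter",
    "voxel_grid_filter",
    "fused_filter",
]


@dataclass
class FilterParams:
    """Parameters of the fused filter chain (defaults match the field rig)."""

    x_range: tuple[float, float] = (-1.25, 1.00)
    z_range: tuple[float, float] = (1.50, 3.00)
    mean_k: int = 60
    stddev_mult: float = 1.0
    leaf_size: float = 0.03

    def __post_init__(self) -> None:
        if self.x_range[0] >= self.x_range[1] or self.z_range[0] >= self.z_range[1]:
            raise ValueError("pass-band intervals must be nonempty")
        if self.mean_k < 1:
            raise ValueError("mean_k must be >= 1")
        if self.leaf_size <= 0:
            raise ValueError("leaf_size must be positive")


def conditional_filter(cloud: PointCloud, params: FilterParams) -> PointCloud:
    """Keep points strictly inside the x/z pass band; y is unconstrained.

    Intervals are open: a point exactly on a bound is removed.  Input order
    is preserved.
    """
    x, z = cloud.points[:, 0], cloud.points[:, 2]
    keep = (
        (x > params.x_range[0]) & (x < params.x_range[1])
        & (z > params.z_range[0]) & (z < params.z_range[1])
    )
    if not keep.any():
        logger.warning("conditional filter removed every point")
    return cloud.select(np.flatnonzero(keep))


def statistical_outlier_filter(cloud: PointCloud, params: FilterParams) -> PointCloud:
    """Drop points whose mean k-NN distance is anomalously large.

    For each point, d̄ᵢ is the mean distance to its ``mean_k`` nearest
    neighbours (the point itself excluded).  With μ, σ the mean and population
    standard deviation of {d̄ᵢ}, points with d̄ᵢ > μ + stddev_mult·σ are
    removed (one-sided).  Survivors keep their input order.
    """
    n = len(cloud)
    if n <= params.mean_k:
        raise ValueError(
            f"cloud has {n} points but mean_k={params.mean_k}; use a smaller mean_k"
        )
    tree = cKDTree(cloud.points)
    # k+1 because the nearest hit of each query is the point itself
    dists, _ = tree.query(cloud.points, k=params.mean_k + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    mu, sigma = mean_d.mean(), mean_d.std()
    # relative epsilon so a perfectly uniform cloud (sigma == 0 up to float
    # round-off) keeps every point
    keep = mean_d <= mu + params.stddev_mult * sigma + 1e-12 * mu
    logger.info("SORF kept %d / %d points", int(keep.sum()), n)
    return cloud.select(np.flatnonzero(keep))


def voxel_grid_filter(cloud: PointCloud, params: FilterParams) -> PointCloud:
    """Downsample to one centroid per occupied cubic voxel of edge leaf_size.

    The grid is anchored at ``floor(min / leaf)`` so the result is independent
    of point order and deterministic.  Output points are ordered by voxel key.
    """
    if len(cloud) == 0:
        return cloud
    leaf = params.leaf_size
    keys = np.floor(cloud.points / leaf).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    sums = np.zeros((len(uniq), 3))
    np.add.at(sums, inverse, cloud.points)
    counts = np.bincount(inverse, minlength=len(uniq)).astype(float)
    centroids = sums / counts[:, None]
    logger.info(
        "VGF compressed %d -> %d points (%.1f%%)",
        len(cloud), len(uniq), 100.0 * (1 - len(uniq) / len(cloud)),
    )
    return PointCloud(centroids)


def fused_filter(
    cloud: PointCloud, params: FilterParams | None = None
) -> PointCloud:
    """Conditional → statistical-outlier → voxel-grid, in that fixed order."""
    params = params or FilterParams()
    stage = conditional_filter(cloud, params)
    counts = [len(cloud), len(stage)]
    if len(stage) == 0:
        logger.warning("fused filter: empty after conditional stage")
        return stage
    if len(stage) > params.mean_k:
        stage = statistical_outlier_filter(stage, params)
    else:
        logger.warning(
            "fused filter: %d points <= mean_k=%d, skipping outlier stage",
            len(stage), params.mean_k,
        )
    counts.append(len(stage))
    if len(stage) == 0:
        logger.warning("fused filter: empty after outlier stage")
        return stage
    stage = voxel_grid_filter(stage, params)
    counts.append(len(stage))
    logger.info("fused filter stage counts: %s", counts)
    return stage
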