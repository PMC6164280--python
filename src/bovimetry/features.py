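"""Surface normals, FPFH/VFH shape descriptors, and library-based matching.

The target-recognition stage decides which segmented cluster is the animal.
Each cluster is summarised by a viewpoint feature histogram (VFH): a single
308-component global descriptor combining

* a **viewpoint component** — 128-bin histogram of the angle between every
  point normal and the direction from the cluster centroid to the sensor
  viewpoint (pose-discriminative, scale-invariant), and
* a **shape component** — an extended fast-point-feature-histogram between the
  centroid (paired with the mean normal) and every point: three 45-bin
  histograms of the Darboux-frame angles (α, φ, θ) plus one 45-bin histogram
  of centroid distances normalised by their maximum; 4 × 45 = 180 bins.

Descriptors of known animal clusters form a feature library; a candidate
cluster matches when the Euclidean distance from its VFH to the nearest
library entry falls below a threshold (small distance = similar).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .core_io import PointCloud

logger = logging.getLogger("bovimetry")

__all__ = [
    "NormalParams",
    "VFH_LENGTH",
    "VFH_VIEWPOINT_BINS",
    "VFH_SHAPE_BINS",
    "estimate_normals",
    "compute_fpfh",
    "compute_vfh",
    "FeatureLibrary",
    "build_feature_library",
    "match_cluster",
    "MatchResult",
    "calibrate_match_threshold",
]

VFH_VIEWPOINT_BINS = 128
VFH_SHAPE_SUBBINS = 45
VFH_SHAPE_BINS = 4 * VFH_SHAPE_SUBBINS       # α, φ, θ, normalised distance
VFH_LENGTH = VFH_VIEWPOINT_BINS + VFH_SHAPE_BINS  # 308
FPFH_BINS_PER_ANGLE = 11


@dataclass
class NormalParams:
    k_neighbors: int = 30
    viewpoint: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.k_neighbors < 3:
            raise ValueError("k_neighbors must be >= 3")
        self.viewpoint = np.asarray(self.viewpoint, dtype=np.float64).reshape(3)


def estimate_normals(cloud: PointCloud, params: NormalParams | None = None) -> PointCloud:
    """Per-point normals from local k-NN plane fits, oriented to the viewpoint.

    The normal at p is the smallest-eigenvalue eigenvector of the covariance of
    its ``k_neighbors`` nearest neighbours, sign-flipped so that
    ``normal · (viewpoint − p) ≥ 0``.  Degenerate (near-collinear)
    neighbourhoods yield NaN normals, which later stages skip.
    """
    params = params or NormalParams()
    n = len(cloud)
    if n <= params.k_neighbors:
        raise ValueError(f"need more than k_neighbors={params.k_neighbors} points, got {n}")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=params.k_neighbors + 1)
    neigh = cloud.points[idx]                       # (n, k+1, 3), includes self
    centred = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centred, centred) / params.k_neighbors
    eigval, eigvec = np.linalg.eigh(cov)
    normals = eigvec[:, :, 0].copy()
    # rank < 2 neighbourhood: two vanishing eigenvalues relative to the spread
    scale = eigval[:, 2]
    degenerate = eigval[:, 1] <= 1e-9 * np.maximum(scale, 1e-300)
    to_vp = params.viewpoint - cloud.points
    flip = np.einsum("ni,ni->n", normals, to_vp) < 0
    normals[flip] *= -1
    normals[degenerate] = np.nan
    if degenerate.any():
        logger.warning("%d degenerate normal neighbourhoods flagged NaN", degenerate.sum())
    out = cloud.copy()
    out.normals = normals
    return out


def _darboux_angles(p_s, n_s, p_t, n_t):
    """Darboux-frame pair features (α, φ, θ) with (p_s, n_s) as source.

    Frame: u = n_s, v = d̂ × u, w = u × v with d̂ the unit source→target
    direction.  α = v·n_t ∈ [−1, 1]; φ = u·d̂ ∈ [−1, 1];
    θ = atan2(w·n_t, u·n_t) ∈ [−π, π].
    """
    d = p_t - p_s
    dist = np.linalg.norm(d, axis=-1)
    dist = np.where(dist == 0, 1.0, dist)
    dhat = d / dist[..., None]
    u = n_s
    v = np.cross(dhat, u)
    vn = np.linalg.norm(v, axis=-1)
    vn = np.where(vn == 0, 1.0, vn)
    v = v / vn[..., None]
    w = np.cross(u, v)
    alpha = np.einsum("...i,...i->...", v, n_t)
    phi = np.einsum("...i,...i->...", u, dhat)
    theta = np.arctan2(
        np.einsum("...i,...i->...", w, n_t), np.einsum("...i,...i->...", u, n_t)
    )
    return alpha, phi, theta


def _hist(values, lo, hi, bins):
    h, _ = np.histogram(np.clip(values, lo, hi - 1e-12 * max(abs(hi), 1)), bins=bins,
                        range=(lo, hi))
    return h.astype(np.float64)


def _percent(h: np.ndarray) -> np.ndarray:
    s = h.sum()
    return h * (100.0 / s) if s > 0 else h


def compute_fpfh(cloud: PointCloud, radius: float = 0.1) -> np.ndarray:
    """Per-point fast point feature histograms, (N, 33), in percent.

    SPFH(p) histograms the (α, φ, θ) angles from p to each neighbour within
    ``radius`` into 3 × 11 bins; FPFH(p) = SPFH(p) + (1/k) Σ_k SPFH(p_k)/ω_k
    with ω_k = ‖p − p_k‖, then each 11-bin block is renormalised to sum 100.
    Points with no neighbour in range get a zero descriptor.
    """
    if cloud.normals is None:
        raise ValueError("compute_fpfh requires normals; call estimate_normals first")
    pts, nrm = cloud.points, cloud.normals
    n = len(pts)
    valid = np.isfinite(nrm).all(axis=1)
    tree = cKDTree(pts)
    neighbor_lists = tree.query_ball_point(pts, radius)
    spfh = np.zeros((n, 3, FPFH_BINS_PER_ANGLE))
    neigh_idx: list[np.ndarray] = []
    for i in range(n):
        nb = np.array([j for j in neighbor_lists[i] if j != i and valid[j]], dtype=int)
        neigh_idx.append(nb)
        if not valid[i] or len(nb) == 0:
            continue
        a, f, t = _darboux_angles(pts[i], nrm[i], pts[nb], nrm[nb])
        spfh[i, 0] = _hist(a, -1.0, 1.0, FPFH_BINS_PER_ANGLE)
        spfh[i, 1] = _hist(f, -1.0, 1.0, FPFH_BINS_PER_ANGLE)
        spfh[i, 2] = _hist(t, -np.pi, np.pi, FPFH_BINS_PER_ANGLE)
    fpfh = np.zeros_like(spfh)
    for i in range(n):
        nb = neigh_idx[i]
        if not valid[i] or len(nb) == 0:
            continue
        w = np.linalg.norm(pts[nb] - pts[i], axis=1)
        w = np.where(w == 0, 1e-12, w)
        fpfh[i] = spfh[i] + (spfh[nb] / w[:, None, None]).sum(axis=0) / len(nb)
        for b in range(3):
            fpfh[i, b] = _percent(fpfh[i, b])
    return fpfh.reshape(n, 3 * FPFH_BINS_PER_ANGLE)


def compute_vfh(cloud: PointCloud, viewpoint=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Global 308-component viewpoint feature histogram of a cluster.

    Layout: ``[viewpoint 128 | α 45 | φ 45 | θ 45 | distance 45]``; the
    viewpoint block and each 45-bin block individually sum to 100.
    """
    if cloud.normals is None:
        raise ValueError("compute_vfh requires normals; call estimate_normals first")
    if len(cloud) < 2:
        raise ValueError("VFH needs at least 2 points")
    viewpoint = np.asarray(viewpoint, dtype=np.float64).reshape(3)
    valid = np.isfinite(cloud.normals).all(axis=1)
    pts, nrm = cloud.points[valid], cloud.normals[valid]
    if len(pts) < 2:
        raise ValueError("VFH needs at least 2 points with valid normals")
    centroid = pts.mean(axis=0)
    radii = np.linalg.norm(pts - centroid, axis=1)
    rmax = radii.max()
    if rmax < 1e-12:
        raise ValueError("degenerate cluster: all points coincident")
    mean_normal = nrm.mean(axis=0)
    mn_norm = np.linalg.norm(mean_normal)
    mean_normal = mean_normal / mn_norm if mn_norm > 1e-12 else np.array([0.0, 0.0, 1.0])

    # shape component: centroid paired with every point
    alpha, phi, theta = _darboux_angles(centroid, mean_normal, pts, nrm)
    shape = np.concatenate([
        _percent(_hist(alpha, -1.0, 1.0, VFH_SHAPE_SUBBINS)),
        _percent(_hist(phi, -1.0, 1.0, VFH_SHAPE_SUBBINS)),
        _percent(_hist(theta, -np.pi, np.pi, VFH_SHAPE_SUBBINS)),
        _percent(_hist(radii / rmax, 0.0, 1.0, VFH_SHAPE_SUBBINS)),
    ])

    # viewpoint component: angle of each normal to the centroid→viewpoint ray
    vdir = viewpoint - centroid
    vn = np.linalg.norm(vdir)
    if vn < 1e-12:
        vdir = np.array([0.0, 0.0, -1.0])
    else:
        vdir = vdir / vn
    cosang = np.clip(nrm @ vdir, -1.0, 1.0)
    vp = _percent(_hist(cosang, -1.0, 1.0, VFH_VIEWPOINT_BINS))

    desc = np.concatenate([vp, shape])
    assert desc.shape == (VFH_LENGTH,)
    return desc


# ---------------------------------------------------------------------------
# feature library
# ---------------------------------------------------------------------------

LIBRARY_FORMAT_VERSION = 1


@dataclass
class MatchResult:
    matched: bool
    label: str | None
    distance: float
    reason: str = ""


@dataclass
class FeatureLibrary:
    """Indexed collection of VFH descriptors of known target clusters."""

    descriptors: np.ndarray           # (M, 308)
    labels: list[str]
    match_threshold: float
    _index: cKDTree | None = None

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        if self.descriptors.ndim != 2 or self.descriptors.shape[1] != VFH_LENGTH:
            raise ValueError(f"descriptors must be (M, {VFH_LENGTH})")
        if len(self.labels) != len(self.descriptors):
            raise ValueError("labels/descriptors length mismatch")
        self._index = cKDTree(self.descriptors)

    def __len__(self) -> int:
        return len(self.descriptors)

    def query(self, descriptor: np.ndarray) -> tuple[float, str]:
        """Distance and label of the nearest library descriptor."""
        d, i = self._index.query(np.asarray(descriptor).reshape(VFH_LENGTH))
        return float(d), self.labels[int(i)]

    def save(self, path) -> None:
        payload = {
            "format": "bovimetry-feature-library",
            "version": LIBRARY_FORMAT_VERSION,
            "descriptor_layout": "viewpoint128|alpha45|phi45|theta45|dist45",
            "match_threshold": self.match_threshold,
            "labels": self.labels,
            "descriptors": self.descriptors.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "FeatureLibrary":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "bovimetry-feature-library":
            raise ValueError(f"{path} is not a feature library file")
        return cls(
            np.array(payload["descriptors"], dtype=np.float64),
            list(payload["labels"]),
            float(payload["match_threshold"]),
        )


def build_feature_library(
    clusters: list[PointCloud],
    normal_params: NormalParams | None = None,
    viewpoint=(0.0, 0.0, 0.0),
    labels: list[str] | None = None,
    match_threshold: float | None = None,
) -> FeatureLibrary:
    """Compute VFH descriptors of known clusters and index them.

    Clusters whose descriptor cannot be computed (degenerate geometry) are
    skipped with a warning.  If ``match_threshold`` is None it is calibrated
    from the library itself via :func:`calibrate_match_threshold`.
    """
    normal_params = normal_params or NormalParams(viewpoint=np.asarray(viewpoint))
    descs, kept_labels, kept_clusters = [], [], []
    for i, cl in enumerate(clusters):
        label = labels[i] if labels else f"cluster-{i}"
        try:
            with_n = cl if cl.normals is not None else estimate_normals(cl, normal_params)
            descs.append(compute_vfh(with_n, viewpoint))
            kept_labels.append(label)
            kept_clusters.append(with_n)
        except ValueError as e:
            logger.warning("skipping degenerate cluster %s: %s", label, e)
    if not descs:
        raise ValueError("no valid cluster to build a library from")
    if match_threshold is None:
        match_threshold = calibrate_match_threshold(
            kept_clusters, viewpoint=viewpoint, seed=0
        )
    return FeatureLibrary(np.array(descs), kept_labels, match_threshold)


def calibrate_match_threshold(
    clusters: list[PointCloud],
    viewpoint=(0.0, 0.0, 0.0),
    jitter_sigma: float = 0.005,
    n_jitter: int = 5,
    seed: int | None = 0,
) -> float:
    """Data-driven match threshold: intra-class mean + 2·std.

    Each library cluster is perturbed ``n_jitter`` times with isotropic
    Gaussian point jitter (default σ = 5 mm); the descriptor distances between
    each original and its perturbed copies form the intra-class distance
    sample, and the threshold is its mean + 2 standard deviations.
    """
    rng = np.random.default_rng(seed)
    dists = []
    for cl in clusters:
        base = cl if cl.normals is not None else estimate_normals(cl)
        ref = compute_vfh(base, viewpoint)
        for _ in range(n_jitter):
            pts = cl.points + rng.normal(0.0, jitter_sigma, cl.points.shape)
            jit = estimate_normals(PointCloud(pts))
            dists.append(np.linalg.norm(compute_vfh(jit, viewpoint) - ref))
    dists = np.array(dists)
    return float(dists.mean() + 2.0 * dists.std())


def match_cluster(
    library: FeatureLibrary,
    cluster: PointCloud,
    threshold: float | None = None,
    viewpoint=(0.0, 0.0, 0.0),
) -> MatchResult:
    """Classify a cluster against the library by nearest-VFH distance.

    Matched iff the minimum Euclidean descriptor distance ≤ threshold
    (library default when None).  Unmatched clusters are dropped from the
    pipeline downstream.
    """
    if len(library) == 0:
        raise ValueError("empty feature library")
    thr = library.match_threshold if threshold is None else threshold
    try:
        with_n = cluster if cluster.normals is not None else estimate_normals(cluster)
        desc = compute_vfh(with_n, viewpoint)
    except ValueError as e:
        return MatchResult(False, None, np.inf, reason=f"degenerate cluster: {e}")
    dist, label = library.query(desc)
    return MatchResult(dist <= thr, label if dist <= thr else None, dist)
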