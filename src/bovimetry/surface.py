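"""Moving-least-squares resampling and greedy projection triangulation.

Registered scans are noisy and unevenly sampled.  MLS projects every point
onto a locally fitted polynomial surface (Gaussian-weighted least squares over
its radius neighbourhood), smoothing the cloud without changing its
cardinality.  The smoothed, oriented cloud is then meshed by greedy
projection: each point's neighbourhood is projected onto its tangent plane and
triangulated locally (2D Delaunay), and locally agreeing, angle-admissible
triangles incident to the point are stitched into a global triangle soup with
a manifold guard (no edge acquires more than two faces).  Mesh vertices are
exactly the input points; no vertices are synthesised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .core_io import PointCloud
from .features import NormalParams, estimate_normals

logger = logging.getLogger("bovimetry")

__all__ = [
    "MlsParams",
    "GptParams",
    "TriangleMesh",
    "mls_resample",
    "greedy_projection_triangulate",
    "mesh_quality",
]


@dataclass
class MlsParams:
    search_radius: float = 0.05
    polynomial_order: int = 2
    gaussian_h: float | None = None   # defaults to search_radius

    def __post_init__(self) -> None:
        if self.search_radius <= 0:
            raise ValueError("search_radius must be positive")
        if self.polynomial_order not in (1, 2):
            raise ValueError("polynomial_order must be 1 or 2")
        if self.gaussian_h is None:
            self.gaussian_h = self.search_radius


@dataclass
class GptParams:
    mu: float = 2.5                   # edge-length multiplier of the NN distance
    search_radius: float = 0.10
    max_nearest_neighbors: int = 100
    min_angle: float = 10.0           # degrees
    max_angle: float = 120.0
    max_surface_angle: float = 45.0

    def __post_init__(self) -> None:
        if not (0 < self.min_angle < self.max_angle < 180):
            raise ValueError("need 0 < min_angle < max_angle < 180")


@dataclass
class TriangleMesh:
    vertices: np.ndarray              # (N, 3) metres
    faces: np.ndarray                 # (M, 3) vertex indices

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            if (np.diff(np.sort(self.faces, axis=1), axis=1) == 0).any():
                raise ValueError("face with repeated vertices")
            key = np.sort(self.faces, axis=1)
            if len(np.unique(key, axis=0)) != len(key):
                raise ValueError("duplicate faces")


# ---------------------------------------------------------------------------
# MLS
# ---------------------------------------------------------------------------

def _design(u: np.ndarray, v: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(u), u, v]
    if order == 2:
        cols += [u * u, u * v, v * v]
    return np.column_stack(cols)


def mls_resample(cloud: PointCloud, params: MlsParams | None = None) -> PointCloud:
    """Project each point onto its local weighted polynomial surface.

    For each point, a weighted reference plane is fitted to the radius
    neighbourhood (Gaussian weights exp(−d²/h²)); heights above that plane are
    then fitted with a bivariate polynomial of the configured order, and the
    point is moved onto the fitted surface.  Output has the same cardinality
    as the input; normals are recomputed from the fitted surfaces.  Points
    whose neighbourhood is too small for the polynomial fall back to order 1,
    then to plane projection.
    """
    params = params or MlsParams()
    pts = cloud.points
    n = len(pts)
    if n <= 10:
        raise ValueError("MLS needs more than 10 points")
    tree = cKDTree(pts)
    neighbor_lists = tree.query_ball_point(pts, params.search_radius)
    out = np.empty_like(pts)
    normals = np.empty_like(pts)
    h2 = params.gaussian_h ** 2
    n_fallback = 0
    for i in range(n):
        nb = np.asarray(neighbor_lists[i], dtype=int)
        if len(nb) < 3:
            out[i] = pts[i]
            normals[i] = np.nan
            n_fallback += 1
            continue
        local = pts[nb]
        d2 = ((local - pts[i]) ** 2).sum(axis=1)
        w = np.exp(-d2 / h2)
        # weighted reference plane
        c = (w[:, None] * local).sum(axis=0) / w.sum()
        centred = local - c
        cov = (w[:, None, None] * np.einsum("ki,kj->kij", centred, centred)).sum(axis=0)
        eigval, eigvec = np.linalg.eigh(cov)
        nvec = eigvec[:, 0]
        e1, e2 = eigvec[:, 2], eigvec[:, 1]
        u, v = centred @ e1, centred @ e2
        wloc = centred @ nvec
        q = pts[i] - c
        qu, qv = q @ e1, q @ e2
        order = params.polynomial_order
        coef = None
        while order >= 1:
            A = _design(u, v, order)
            if len(nb) >= A.shape[1]:
                Aw = A * w[:, None]
                try:
                    coef, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ wloc, rcond=None)
                    break
                except np.linalg.LinAlgError:
                    pass
            order -= 1
            n_fallback += 1
        if coef is None:     # plane projection fallback
            out[i] = c + qu * e1 + qv * e2
            normals[i] = nvec
            continue
        # surface height and gradient at the query's (u, v)
        if order == 2:
            height = coef @ np.array([1.0, qu, qv, qu * qu, qu * qv, qv * qv])
            gu = coef[1] + 2 * coef[3] * qu + coef[4] * qv
            gv = coef[2] + coef[4] * qu + 2 * coef[5] * qv
        else:
            height = coef @ np.array([1.0, qu, qv])
            gu, gv = coef[1], coef[2]
        out[i] = c + qu * e1 + qv * e2 + height * nvec
        nrm = nvec - gu * e1 - gv * e2
        normals[i] = nrm / np.linalg.norm(nrm)
    if n_fallback:
        logger.info("MLS: %d points used a reduced-order fallback", n_fallback)
    # keep normal orientation consistent with any existing normals
    if cloud.normals is not None:
        flip = np.einsum("ni,ni->n", normals, cloud.normals) < 0
        normals[flip] *= -1
    return PointCloud(out, normals)


# ---------------------------------------------------------------------------
# greedy projection triangulation
# ---------------------------------------------------------------------------

def _triangle_angles(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Internal angles (degrees) of triangle abc."""
    la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c), np.linalg.norm(a - b))
    def ang(opp, s1, s2):
        cosv = np.clip((s1 * s1 + s2 * s2 - opp * opp) / (2 * s1 * s2), -1, 1)
        return np.degrees(np.arccos(cosv))
    return np.array([ang(la, lb, lc), ang(lb, la, lc), ang(lc, la, lb)])


def greedy_projection_triangulate(
    cloud: PointCloud, params: GptParams | None = None
) -> TriangleMesh:
    """Mesh an oriented cloud by per-point tangent-plane Delaunay stitching.

    For each point, neighbours within ``min(search_radius, mu · d_nn)`` are
    projected onto the point's tangent plane and Delaunay-triangulated;
    triangles incident to the point that satisfy the angle and surface-angle
    bounds become candidates.  A candidate is accepted when at least two of
    its three vertices propose it (local agreement), and a final greedy pass
    rejects any triangle that would give an edge more than two incident faces,
    so the output has no non-manifold edges by construction.  Vertices are the
    input points; isolated points are left unmeshed (logged).
    """
    params = params or GptParams()
    if cloud.normals is None:
        raise ValueError("triangulation requires normals")
    pts = cloud.points
    nrm = cloud.normals
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    # deterministic symmetry-breaking jitter (triangulation only) so that
    # cocircular configurations (e.g. regular grids) triangulate identically
    # in every local frame
    span = float(np.ptp(pts, axis=0).max()) or 1.0
    jit_pts = pts + np.random.default_rng(0).uniform(-1, 1, pts.shape) * (1e-7 * span)
    tree = cKDTree(jit_pts)
    d_nn = tree.query(jit_pts, k=2)[0][:, 1]
    cos_max_surf = np.cos(np.radians(params.max_surface_angle))
    votes: dict[tuple[int, int, int], int] = {}
    valid_normal = np.isfinite(nrm).all(axis=1)
    for i in range(n):
        if not valid_normal[i]:
            continue
        r = min(params.search_radius, params.mu * d_nn[i])
        nb = tree.query_ball_point(jit_pts[i], r)
        nb = [j for j in nb if j != i and valid_normal[j]]
        if len(nb) > params.max_nearest_neighbors:
            order = np.argsort(np.linalg.norm(jit_pts[nb] - jit_pts[i], axis=1))
            nb = [nb[k] for k in order[: params.max_nearest_neighbors]]
        if len(nb) < 2:
            continue
        nb = np.array(nb, dtype=int)
        # restrict to locally smooth neighbours
        nb = nb[np.abs(nrm[nb] @ nrm[i]) >= cos_max_surf]
        if len(nb) < 2:
            continue
        ni = nrm[i]
        e1 = np.cross(ni, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(ni, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(ni, e1)
        ids = np.concatenate([[i], nb])
        rel = jit_pts[ids] - jit_pts[i]
        uv = np.column_stack([rel @ e1, rel @ e2])
        try:
            tri = Delaunay(uv)
        except QhullError:
            continue
        for simplex in tri.simplices:
            if 0 not in simplex:
                continue
            tri_ids = ids[simplex]
            a, b, c = pts[tri_ids]
            angles = _triangle_angles(a, b, c)
            if angles.min() < params.min_angle or angles.max() > params.max_angle:
                continue
            key = tuple(sorted(int(t) for t in tri_ids))
            votes[key] = votes.get(key, 0) + 1
    # local agreement: at least two of the three vertices proposed the triangle
    candidates = sorted(k for k, v in votes.items() if v >= 2)
    # manifold guard: no edge may exceed two incident faces
    edge_load: dict[tuple[int, int], int] = {}
    faces = []
    for tri_key in candidates:
        edges = [(tri_key[0], tri_key[1]), (tri_key[0], tri_key[2]), (tri_key[1], tri_key[2])]
        if any(edge_load.get(e, 0) >= 2 for e in edges):
            continue
        for e in edges:
            edge_load[e] = edge_load.get(e, 0) + 1
        faces.append(tri_key)
    mesh = TriangleMesh(pts, np.array(faces, dtype=int) if faces else np.empty((0, 3), int))
    used = np.zeros(n, bool)
    if len(mesh.faces):
        used[mesh.faces.ravel()] = True
    n_isolated = int((~used).sum())
    if n_isolated:
        logger.info("GPT left %d isolated/unmeshed points", n_isolated)
    return mesh


def mesh_quality(mesh: TriangleMesh) -> dict:
    """Edge-incidence audit of a triangle mesh.

    Boundary edge: exactly one incident face.  Non-manifold edge: more than
    two incident faces.  ``boundary_edge_fraction`` is boundary edges over all
    edges (0 for an empty mesh).
    """
    faces = mesh.faces
    if len(faces) == 0:
        return {"n_vertices": len(mesh.vertices), "n_faces": 0,
                "boundary_edge_fraction": 0.0, "non_manifold_edge_count": 0}
    edges = np.vstack([faces[:, [0, 1]], faces[:, [0, 2]], faces[:, [1, 2]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return {
        "n_vertices": len(mesh.vertices),
        "n_faces": len(faces),
        "boundary_edge_fraction": float((counts == 1).sum() / len(counts)),
        "non_manifold_edge_count": int((counts > 2).sum()),
    }
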