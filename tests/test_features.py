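"""Normal estimation, FPFH/VFH descriptors, library matching."""

import numpy as np
import pytest

from bovimetry.core_io import PointCloud, RigidTransform, apply_transform
from bovimetry.features import (
    VFH_LENGTH,
    FeatureLibrary,
    MatchResult,
    NormalParams,
    build_feature_library,
    calibrate_match_threshold,
    compute_fpfh,
    compute_vfh,
    estimate_normals,
    match_cluster,
)


def plane_cloud(rng, n=300, extent=1.0):
    pts = np.column_stack([
        rng.uniform(-extent, extent, n), rng.uniform(-extent, extent, n), np.zeros(n)
    ])
    return PointCloud(pts)


def sphere_cloud(rng, n=800, r=1.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return PointCloud(v * r)


class TestEstimateNormals:
    def test_plane_normals_point_to_viewpoint(self, rng):
        cloud = plane_cloud(rng)
        out = estimate_normals(cloud, NormalParams(viewpoint=(0, 0, 5.0)))
        angles = np.degrees(np.arccos(np.clip(out.normals @ [0, 0, 1], -1, 1)))
        assert angles.max() < 1.0

    def test_sphere_normals_are_radial(self, rng):
        cloud = sphere_cloud(rng, n=3000)
        out = estimate_normals(cloud, NormalParams(viewpoint=(0, 0, 0)))
        radial = cloud.points / np.linalg.norm(cloud.points, axis=1, keepdims=True)
        # viewpoint at the centre orients normals inward
        cos = np.abs(np.einsum("ni,ni->n", out.normals, radial))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))).max() < 5.0

    def test_collinear_neighborhood_flagged_nan(self):
        line = np.outer(np.linspace(0, 1, 10), [1.0, 0, 0])
        out = estimate_normals(PointCloud(line), NormalParams(k_neighbors=3))
        assert np.isnan(out.normals).all()

    def test_unit_length(self, rng):
        out = estimate_normals(sphere_cloud(rng, 200))
        norms = np.linalg.norm(out.normals, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)


class TestFPFH:
    def test_shape_and_block_normalization(self, rng):
        cloud = estimate_normals(sphere_cloud(rng, 300))
        fpfh = compute_fpfh(cloud, radius=0.5)
        assert fpfh.shape == (300, 33)
        sums = fpfh.reshape(300, 3, 11).sum(axis=2)
        np.testing.assert_allclose(sums, 100.0, atol=1e-6)

    def test_plane_concentrates_angles_in_single_bins(self, rng):
        cloud = plane_cloud(rng, 200)
        cloud.normals = np.tile([0.0, 0.0, 1.0], (200, 1))
        fpfh = compute_fpfh(cloud, radius=0.4).reshape(200, 3, 11)
        ok = fpfh.sum(axis=(1, 2)) > 0          # skip any isolated points
        assert ok.sum() > 150
        # alpha = v·n_t = 0 and phi = u·d = 0 for coplanar identical normals
        assert (fpfh[ok, 0].argmax(axis=1) == 5).all()
        assert (fpfh[ok, 1].argmax(axis=1) == 5).all()
        np.testing.assert_allclose(fpfh[ok, 0].max(axis=1), 100.0, atol=1e-9)

    def test_two_point_darboux_oracle(self):
        """Hand-computed Darboux angles for an orthogonal two-point setup.

        p1=(0,0,0), n1=+z; p2=(1,0,0), n2=+y.  From p1: u=+z, v=d̂×u=(0,−1,0),
        w=u×v=(1,0,0); alpha=v·n2=−1 (bin 0), phi=u·d̂=0 (bin 5),
        theta=atan2(w·n2, u·n2)=atan2(0,0)=0 (bin 5).  The symmetric pair from
        p2 gives the same bins, so the FPFH inherits them exactly.
        """
        cloud = PointCloud([[0, 0, 0], [1.0, 0, 0]],
                           normals=[[0, 0, 1.0], [0, 1.0, 0]])
        fpfh = compute_fpfh(cloud, radius=2.0).reshape(2, 3, 11)
        for i in range(2):
            assert fpfh[i, 0, 0] == 100.0      # alpha = −1
            assert fpfh[i, 1, 5] == 100.0      # phi = 0
            assert fpfh[i, 2, 5] == 100.0      # theta = 0

    def test_rigid_invariance(self, rng):
        cloud = estimate_normals(sphere_cloud(rng, 250), NormalParams(viewpoint=(0, 0, 3)))
        T = RigidTransform.from_axis_angle((1, 2, 3), 0.9, (0.4, -0.2, 1.0))
        moved = apply_transform(cloud, T)
        a = compute_fpfh(cloud, radius=0.6)
        b = compute_fpfh(moved, radius=0.6)
        assert np.abs(a - b).max() < 1e-6

    def test_isolated_point_gets_zero_descriptor(self, rng):
        pts = np.vstack([sphere_cloud(rng, 100).points, [[50.0, 0, 0]]])
        nrm = np.vstack([np.ones((100, 3)) / np.sqrt(3), [[0, 0, 1.0]]])
        fpfh = compute_fpfh(PointCloud(pts, nrm), radius=0.5)
        assert (fpfh[-1] == 0).all()


class TestVFH:
    def test_length_and_block_structure(self, clean_segmented):
        *_, body, _ = clean_segmented
        desc = compute_vfh(estimate_normals(body))
        assert desc.shape == (VFH_LENGTH,)
        assert VFH_LENGTH == 308
        assert desc[:128].sum() == pytest.approx(100.0, abs=1e-6)
        for b in range(4):
            block = desc[128 + 45 * b : 128 + 45 * (b + 1)]
            assert block.sum() == pytest.approx(100.0, abs=1e-6)
        assert (desc >= 0).all()

    def test_rigid_invariance_with_cotransformed_viewpoint(self, rng):
        cloud = estimate_normals(sphere_cloud(rng, 300), NormalParams(viewpoint=(0, 0, 5)))
        T = RigidTransform.from_axis_angle((0, 1, 1), 0.6, (1.0, 0.5, -0.3))
        moved = apply_transform(cloud, T)
        a = compute_vfh(cloud, viewpoint=(0, 0, 5))
        b = compute_vfh(moved, viewpoint=T.apply([[0, 0, 5.0]])[0])
        assert np.abs(a - b).max() < 1e-6

    def test_distance_block_scale_invariant(self, rng):
        cloud = estimate_normals(sphere_cloud(rng, 300))
        centroid = cloud.points.mean(axis=0)
        scaled = PointCloud((cloud.points - centroid) * 2 + centroid, cloud.normals)
        a = compute_vfh(cloud)[128 + 135 :]
        b = compute_vfh(scaled)[128 + 135 :]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_degenerate_cluster_raises(self):
        cloud = PointCloud(np.zeros((5, 3)), normals=np.tile([0, 0, 1.0], (5, 1)))
        with pytest.raises(ValueError, match="coincident"):
            compute_vfh(cloud)


class TestFeatureLibrary:
    def test_round_trip_and_self_match(self, tmp_path, rng):
        clusters = [sphere_cloud(rng, 200, r) for r in (0.5, 0.8, 1.1, 1.4, 1.7)]
        lib = build_feature_library(clusters, match_threshold=10.0)
        assert len(lib) == 5
        lib.save(tmp_path / "lib.json")
        back = FeatureLibrary.load(tmp_path / "lib.json")
        np.testing.assert_array_equal(back.descriptors, lib.descriptors)
        assert back.labels == lib.labels
        d, label = back.query(lib.descriptors[2])
        assert d == 0.0 and label == "cluster-2"

    def test_index_matches_exhaustive_scan(self, rng):
        descs = rng.uniform(0, 5, size=(50, VFH_LENGTH))
        lib = FeatureLibrary(descs, [f"c{i}" for i in range(50)], 1.0)
        for _ in range(20):
            q = rng.uniform(0, 5, VFH_LENGTH)
            d, label = lib.query(q)
            brute = np.linalg.norm(descs - q, axis=1)
            assert label == f"c{brute.argmin()}"
            assert d == pytest.approx(brute.min())

    def test_member_matches_at_distance_zero(self, feature_library, distorted_segmented):
        *_, body, _ = distorted_segmented
        res = match_cluster(feature_library, body)
        assert isinstance(res, MatchResult)
        assert res.matched

    def test_jittered_member_matches(self, rng, distorted_segmented, feature_library):
        *_, body, _ = distorted_segmented
        jit = PointCloud(body.points + rng.normal(0, 0.005, body.points.shape))
        assert match_cluster(feature_library, jit).matched

    def test_noise_sphere_rejected(self, rng, feature_library):
        ball = sphere_cloud(rng, 600, r=0.5)
        res = match_cluster(feature_library, ball)
        assert not res.matched

    def test_calibrated_threshold_separates_intra_from_inter(self, rng, clean_segmented):
        *_, body, _ = clean_segmented
        thr = calibrate_match_threshold([body], seed=0)
        intra = np.linalg.norm(
            compute_vfh(estimate_normals(PointCloud(
                body.points + rng.normal(0, 0.005, body.points.shape))))
            - compute_vfh(estimate_normals(body))
        )
        inter = np.linalg.norm(
            compute_vfh(estimate_normals(sphere_cloud(rng, 500)))
            - compute_vfh(estimate_normals(body))
        )
        assert intra <= thr < inter
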