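"""Point-cloud container, transforms, kd-tree and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bovimetry.core_io import (
    FormatError,
    KDTree,
    PointCloud,
    RigidTransform,
    apply_transform,
    build_kdtree,
    load_cloud,
    load_mesh,
    write_cloud,
    write_mesh,
)


def random_cloud(rng, n=50, normals=False):
    pts = rng.normal(size=(n, 3))
    if normals:
        nrm = rng.normal(size=(n, 3))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        return PointCloud(pts, nrm)
    return PointCloud(pts)


class TestPointCloud:
    def test_organized_dims_must_multiply_to_n(self):
        with pytest.raises(ValueError):
            PointCloud(np.zeros((5, 3)), width=2, height=2)

    def test_drop_invalid_removes_nan_rows(self):
        pts = np.array([[0, 0, 1], [np.nan, 0, 1], [1, 1, 1.0]])
        cloud = PointCloud(pts, width=3, height=1).drop_invalid()
        assert len(cloud) == 2
        assert not cloud.is_organized  # grid broken by the drop


class TestRigidTransform:
    def test_rejects_non_orthonormal_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_quarter_turn_about_z_maps_x_to_y(self):
        T = RigidTransform.from_axis_angle((0, 0, 1), np.pi / 2)
        np.testing.assert_allclose(T.apply([[1, 0, 0]]), [[0, 1, 0]], atol=1e-12)

    def test_inverse_composes_to_identity(self, rng):
        T = RigidTransform.from_axis_angle(rng.normal(size=3), 0.7, rng.normal(size=3))
        I = T @ T.inverse()
        np.testing.assert_allclose(I.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(I.translation, 0, atol=1e-12)

    def test_composition_associative_and_distance_preserving(self, rng):
        a = RigidTransform.from_axis_angle((1, 0, 0), 0.3, (0.1, 0, 0))
        b = RigidTransform.from_axis_angle((0, 1, 0), -0.8, (0, 0.2, 0))
        c = RigidTransform.from_axis_angle((0, 0, 1), 1.1, (0, 0, -0.4))
        np.testing.assert_allclose(
            ((a @ b) @ c).as_matrix(), (a @ (b @ c)).as_matrix(), atol=1e-12
        )
        cloud = random_cloud(rng, 40)
        moved = apply_transform(cloud, a @ b)
        d0 = np.linalg.norm(cloud.points[:, None] - cloud.points[None], axis=-1)
        d1 = np.linalg.norm(moved.points[:, None] - moved.points[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_apply_transform_rotates_normals(self, rng):
        cloud = random_cloud(rng, 20, normals=True)
        T = RigidTransform.from_axis_angle((0, 1, 0), 1.0, (1, 2, 3))
        out = apply_transform(cloud, T)
        np.testing.assert_allclose(
            np.linalg.norm(out.normals, axis=1), 1.0, atol=1e-9
        )


class TestKDTree:
    def test_self_query_returns_zero_distance(self, rng):
        cloud = random_cloud(rng, 30)
        tree = build_kdtree(cloud)
        d, i = tree.knn(cloud.points[7], k=1)
        assert d[0] == 0 and i[0] == 7

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            KDTree(PointCloud(np.empty((0, 3))))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_knn_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-1, 1, size=(200, 3))
        tree = KDTree(PointCloud(pts))
        q = rng.uniform(-1, 1, size=3)
        d, i = tree.knn(q, k=5)
        brute = np.argsort(np.linalg.norm(pts - q, axis=1))[:5]
        np.testing.assert_allclose(
            np.sort(d), np.sort(np.linalg.norm(pts[brute] - q, axis=1)), atol=1e-12
        )

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_radius_query_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-1, 1, size=(150, 3))
        tree = KDTree(PointCloud(pts))
        q = rng.uniform(-1, 1, size=3)
        got = set(tree.radius(q, 0.5).tolist())
        want = set(np.flatnonzero(np.linalg.norm(pts - q, axis=1) <= 0.5).tolist())
        assert got == want


class TestFileIO:
    @pytest.mark.parametrize("fmt", ["pcd", "ply"])
    @pytest.mark.parametrize("binary", [False, True])
    @pytest.mark.parametrize("with_normals", [False, True])
    def test_round_trip(self, tmp_path, rng, fmt, binary, with_normals):
        cloud = random_cloud(rng, 100, normals=with_normals)
        path = tmp_path / f"c.{fmt}"
        write_cloud(cloud, path, binary=binary)
        back = load_cloud(path)
        np.testing.assert_allclose(back.points, cloud.points, atol=1e-6)
        if with_normals:
            np.testing.assert_allclose(back.normals, cloud.normals, atol=1e-6)

    def test_large_round_trip_preserves_coordinates(self, tmp_path, rng):
        cloud = random_cloud(rng, 10_000)
        write_cloud(cloud, tmp_path / "big.pcd", binary=True)
        np.testing.assert_allclose(
            load_cloud(tmp_path / "big.pcd").points, cloud.points, atol=1e-6
        )

    def test_pcd_nan_rows_dropped(self, tmp_path):
        text = (
            "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
            "WIDTH 3\nHEIGHT 1\nPOINTS 3\nDATA ascii\n"
            "0 0 1\nnan nan nan\n1 2 3\n"
        )
        p = tmp_path / "nan.pcd"
        p.write_text(text)
        cloud = load_cloud(p)
        assert len(cloud) == 2

    def test_malformed_pcd_header_raises(self, tmp_path):
        p = tmp_path / "bad.pcd"
        p.write_text("VERSION 0.7\nFIELDS x y z\nnot a header line at all\n" * 40)
        with pytest.raises(FormatError):
            load_cloud(p)

    def test_unsupported_encoding_raises(self, tmp_path):
        p = tmp_path / "bad.pcd"
        p.write_text(
            "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
            "WIDTH 1\nHEIGHT 1\nPOINTS 1\nDATA binary_compressed\n"
        )
        with pytest.raises(FormatError):
            load_cloud(p)

    def test_single_point_pcd_is_valid(self, tmp_path):
        write_cloud(PointCloud([[1.0, 2.0, 3.0]]), tmp_path / "one.pcd")
        header = (tmp_path / "one.pcd").read_text()
        assert "POINTS 1" in header

    def test_ply_normals_declared_in_header(self, tmp_path, rng):
        cloud = random_cloud(rng, 5, normals=True)
        write_cloud(cloud, tmp_path / "n.ply")
        head = (tmp_path / "n.ply").read_text().split("end_header")[0]
        for prop in ("nx", "ny", "nz"):
            assert f"property float {prop}" in head

    @pytest.mark.parametrize("binary", [False, True])
    def test_mesh_round_trip_and_trimesh_oracle(self, tmp_path, binary):
        trimesh = pytest.importorskip("trimesh")
        verts = PointCloud([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        faces = np.array([[0, 1, 2], [0, 1, 3]])
        path = tmp_path / "m.ply"
        write_mesh(verts, faces, path, binary=binary)
        back_cloud, back_faces = load_mesh(path)
        np.testing.assert_allclose(back_cloud.points, verts.points, atol=1e-6)
        np.testing.assert_array_equal(back_faces, faces)
        # independent reader agrees on geometry
        tm = trimesh.load(str(path), process=False)
        np.testing.assert_allclose(np.asarray(tm.vertices), verts.points, atol=1e-6)
        np.testing.assert_array_equal(np.asarray(tm.faces), faces)

    def test_organized_scan_preserves_grid_dims(self, clean_scene, tmp_path):
        scan, _, _ = clean_scene
        assert scan.cloud.width == 176 and scan.cloud.height == 132
        assert len(scan.cloud) == 176 * 132
        valid, _ = scan.valid()
        assert len(valid) <= 23232
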