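"""Point-cloud data model, rigid transforms, kd-tree search and PCD/PLY I/O.

Every pipeline stage operates on :class:`PointCloud`, an array of 3D points in
metres expressed in the sensor frame (x right, y down, z along the optical /
range axis).  Clouds coming straight off a time-of-flight sensor are
*organized* — laid out on the ``width × height`` pixel grid — until invalid
(NaN) returns are dropped.

File formats supported are PCD v0.7 (``ascii`` and ``binary`` encodings) and
PLY (``ascii`` and ``binary_little_endian``), carrying ``x y z`` and optional
``normal_x normal_y normal_z`` / ``nx ny nz`` per-point fields.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("bovimetry")

__all__ = [
    "PointCloud",
    "RigidTransform",
    "KDTree",
    "load_cloud",
    "write_cloud",
    "build_kdtree",
    "apply_transform",
    "FormatError",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported point-cloud files."""


@dataclass
class PointCloud:
    """A set of 3D points in metres with optional unit normals.

    Parameters
    ----------
    points : (N, 3) float array
        Cartesian coordinates in the sensor frame.
    normals : (N, 3) float array, optional
        Per-point unit normals.  Rows may be NaN where estimation failed.
    width, height : int, optional
        Grid dimensions for organized (sensor-grid) clouds; ``width * height``
        must equal ``N`` when both are set.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    width: int | None = None
    height: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
            if len(self.normals) != len(self.points):
                raise ValueError("normals and points must have equal length")
        if (self.width is None) != (self.height is None):
            raise ValueError("width and height must be set together")
        if self.width is not None and self.width * self.height != len(self.points):
            raise ValueError(
                f"organized dims {self.width}x{self.height} != {len(self.points)} points"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_organized(self) -> bool:
        return self.width is not None

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.points.copy(),
            None if self.normals is None else self.normals.copy(),
            self.width,
            self.height,
        )

    def select(self, indices: np.ndarray) -> "PointCloud":
        """Sub-cloud of the given point indices (drops organized structure)."""
        idx = np.asarray(indices)
        return PointCloud(
            self.points[idx],
            None if self.normals is None else self.normals[idx],
        )

    def drop_invalid(self) -> "PointCloud":
        """Remove rows with any non-finite coordinate, logging the count.

        Organized structure is preserved only when nothing was dropped.
        """
        valid = np.isfinite(self.points).all(axis=1)
        n_bad = int((~valid).sum())
        if n_bad == 0:
            return self
        logger.info("dropped %d invalid (NaN/inf) points of %d", n_bad, len(self))
        return self.select(np.flatnonzero(valid))


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p -> R p + t.

    ``rotation`` is a 3x3 orthonormal matrix with det +1; ``translation`` a
    3-vector in metres.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has det -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(
        cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        """Rodrigues rotation about ``axis`` by ``angle_rad`` plus translation."""
        a = np.asarray(axis, dtype=np.float64)
        a = a / np.linalg.norm(a)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=np.float64))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts) @ self.rotation.T + self.translation


class KDTree:
    """Spatial index over a cloud; thin wrapper around scipy's cKDTree."""

    def __init__(self, cloud: PointCloud | np.ndarray):
        pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud)
        if len(pts) == 0:
            raise ValueError("cannot index an empty cloud")
        self._pts = pts
        self._tree = cKDTree(pts)

    def knn(self, query: np.ndarray, k: int):
        """Distances and indices of the k nearest points to ``query``."""
        d, i = self._tree.query(np.asarray(query), k=k)
        return np.atleast_1d(d), np.atleast_1d(i)

    def radius(self, query: np.ndarray, r: float) -> np.ndarray:
        """Indices of all points within Euclidean distance ``r`` (inclusive)."""
        return np.asarray(self._tree.query_ball_point(np.asarray(query), r), dtype=int)

    @property
    def scipy_tree(self) -> cKDTree:
        return self._tree


def build_kdtree(cloud: PointCloud) -> KDTree:
    return KDTree(cloud)


def apply_transform(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Map points p -> Rp + t and normals n -> Rn."""
    out = cloud.copy()
    out.points = transform.apply(cloud.points)
    if cloud.normals is not None:
        out.normals = cloud.normals @ transform.rotation.T
    return out


# ---------------------------------------------------------------------------
# PCD
# ---------------------------------------------------------------------------

_PCD_TYPE = {("F", 4): "f", ("F", 8): "d", ("I", 4): "i", ("U", 4): "I"}


def _parse_pcd_header(fh):
    header = {}
    lines_read = 0
    while True:
        raw = fh.readline()
        if not raw:
            raise FormatError("PCD header ended before DATA line")
        lines_read += 1
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        key = parts[0].upper()
        header[key] = parts[1:]
        if key == "DATA":
            break
        if lines_read > 100:
            raise FormatError(f"runaway PCD header near line: {line!r}")
    for req in ("FIELDS", "SIZE", "TYPE", "POINTS", "DATA"):
        if req not in header:
            raise FormatError(f"PCD header missing {req}")
    return header


def _load_pcd(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        header = _parse_pcd_header(fh)
        fields = [f.lower() for f in header["FIELDS"]]
        sizes = [int(s) for s in header["SIZE"]]
        types = header["TYPE"]
        counts = [int(c) for c in header.get("COUNT", ["1"] * len(fields))]
        if any(c != 1 for c in counts):
            raise FormatError("PCD COUNT != 1 unsupported")
        n = int(header["POINTS"][0])
        width = int(header["WIDTH"][0]) if "WIDTH" in header else n
        height = int(header["HEIGHT"][0]) if "HEIGHT" in header else 1
        encoding = header["DATA"][0].lower()
        if encoding == "ascii":
            data = np.loadtxt(fh, dtype=np.float64, ndmin=2, max_rows=n)
            if data.shape[1] != len(fields):
                raise FormatError(
                    f"ascii PCD row width {data.shape[1]} != FIELDS count {len(fields)}"
                )
        elif encoding == "binary":
            fmt = "<" + "".join(
                _PCD_TYPE.get((t, s), None) or _bad_pcd_type(t, s)
                for t, s in zip(types, sizes)
            )
            row = struct.calcsize(fmt)
            buf = fh.read(row * n)
            if len(buf) < row * n:
                raise FormatError("binary PCD truncated")
            data = np.array(
                [struct.unpack_from(fmt, buf, i * row) for i in range(n)],
                dtype=np.float64,
            ).reshape(n, len(fields))
        else:
            raise FormatError(f"unsupported PCD DATA encoding: {encoding}")
    return _assemble_cloud(data, fields, width, height, path)


def _bad_pcd_type(t, s):
    raise FormatError(f"unsupported PCD field TYPE/SIZE {t}/{s}")


def _assemble_cloud(data, fields, width, height, path) -> PointCloud:
    try:
        cols = [fields.index(a) for a in "xyz"]
    except ValueError as e:
        raise FormatError(f"{path}: missing coordinate field: {e}") from None
    pts = data[:, cols]
    normals = None
    for trio in (("normal_x", "normal_y", "normal_z"), ("nx", "ny", "nz")):
        if all(f in fields for f in trio):
            normals = data[:, [fields.index(f) for f in trio]]
            break
    organized = width is not None and height is not None and height > 1
    cloud = PointCloud(
        pts, normals, width if organized else None, height if organized else None
    )
    clean = cloud.drop_invalid()
    return clean


def _write_pcd(cloud: PointCloud, path: Path, binary: bool = False) -> None:
    has_n = cloud.normals is not None
    fields = "x y z" + (" normal_x normal_y normal_z" if has_n else "")
    ncol = 6 if has_n else 3
    width = cloud.width if cloud.is_organized else len(cloud)
    height = cloud.height if cloud.is_organized else 1
    data = (
        np.hstack([cloud.points, cloud.normals]) if has_n else cloud.points
    )
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        f"FIELDS {fields}\n"
        f"SIZE {' '.join(['4'] * ncol)}\n"
        f"TYPE {' '.join(['F'] * ncol)}\n"
        f"COUNT {' '.join(['1'] * ncol)}\n"
        f"WIDTH {width}\nHEIGHT {height}\n"
        "VIEWPOINT 0 0 0 1 0 0 0\n"
        f"POINTS {len(cloud)}\n"
        f"DATA {'binary' if binary else 'ascii'}\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(data.astype("<f4").tobytes())
        else:
            np.savetxt(fh, data, fmt="%.9g")


# ---------------------------------------------------------------------------
# PLY
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
    "short": "<i2", "ushort": "<u2", "char": "<i1", "uchar": "<u1",
    "int8": "<i1", "uint8": "<u1", "int16": "<i2", "uint16": "<u2",
}


def _load_ply(path: Path):
    """Parse PLY vertices (and faces, if present).

    Returns ``(cloud, faces-or-None)``; faces are an (M, 3) int array.
    """
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        elements = []  # (name, count, [(prop_name, dtype) or ('list', idx_t, val_t, name)])
        while True:
            line = fh.readline()
            if not line:
                raise FormatError("PLY header ended before end_header")
            tokens = line.decode("ascii", errors="replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
                if fmt not in ("ascii", "binary_little_endian"):
                    raise FormatError(f"unsupported PLY format: {fmt}")
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    elements[-1][2].append(("list", tokens[2], tokens[3], tokens[4]))
                else:
                    elements[-1][2].append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        verts = normals = faces = None
        for name, count, props in elements:
            if name == "vertex":
                pnames = [p[0] for p in props]
                if fmt == "ascii":
                    rows = np.array(
                        [fh.readline().split() for _ in range(count)], dtype=np.float64
                    )
                else:
                    dt = np.dtype([(p[0], _PLY_DTYPES[p[1]]) for p in props])
                    rec = np.frombuffer(fh.read(dt.itemsize * count), dtype=dt)
                    rows = np.vstack([rec[p[0]] for p in props]).T.astype(np.float64)
                verts = rows[:, [pnames.index(a) for a in "xyz"]]
                for trio in (("nx", "ny", "nz"), ("normal_x", "normal_y", "normal_z")):
                    if all(t in pnames for t in trio):
                        normals = rows[:, [pnames.index(t) for t in trio]]
            elif name == "face":
                fl = []
                if fmt == "ascii":
                    for _ in range(count):
                        vals = fh.readline().split()
                        k = int(vals[0])
                        fl.append([int(v) for v in vals[1 : 1 + k]])
                else:
                    _, idx_t, val_t, _ = props[0]
                    idt, vdt = np.dtype(_PLY_DTYPES[idx_t]), np.dtype(_PLY_DTYPES[val_t])
                    for _ in range(count):
                        k = int(np.frombuffer(fh.read(idt.itemsize), dtype=idt)[0])
                        fl.append(
                            np.frombuffer(fh.read(vdt.itemsize * k), dtype=vdt).tolist()
                        )
                if any(len(f) != 3 for f in fl):
                    raise FormatError("non-triangular PLY faces unsupported")
                faces = np.array(fl, dtype=int) if fl else np.empty((0, 3), int)
        if verts is None:
            raise FormatError(f"{path}: PLY has no vertex element")
    cloud = PointCloud(verts, normals).drop_invalid()
    return cloud, faces


def _write_ply(
    cloud: PointCloud,
    path: Path,
    faces: np.ndarray | None = None,
    binary: bool = False,
) -> None:
    has_n = cloud.normals is not None
    props = ["property float x", "property float y", "property float z"]
    if has_n:
        props += ["property float nx", "property float ny", "property float nz"]
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {len(cloud)}"] + props
    if faces is not None:
        header += [f"element face {len(faces)}",
                   "property list uchar int vertex_indices"]
    header.append("end_header")
    data = np.hstack([cloud.points, cloud.normals]) if has_n else cloud.points
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.astype("<f4").tobytes())
            if faces is not None:
                for f in faces:
                    fh.write(struct.pack("<B3i", 3, *(int(v) for v in f)))
        else:
            np.savetxt(fh, data, fmt="%.9g")
            if faces is not None:
                np.savetxt(
                    fh,
                    np.hstack([np.full((len(faces), 1), 3), faces]),
                    fmt="%d",
                )


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pcd", "ply"):
        return suffix
    raise FormatError(f"cannot infer format from extension of {path}")


def load_cloud(path, format: str = "auto") -> PointCloud:
    """Read a PCD or PLY file into a :class:`PointCloud`.

    NaN points are dropped (count logged).  Organized grid dimensions from a
    PCD ``WIDTH``/``HEIGHT`` survive only when every row was valid.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pcd":
        return _load_pcd(path)
    if fmt == "ply":
        return _load_ply(path)[0]
    raise FormatError(f"unsupported format: {fmt}")


def load_mesh(path):
    """Read a PLY mesh, returning ``(PointCloud, (M,3) face indices)``."""
    cloud, faces = _load_ply(Path(path))
    if faces is None:
        raise FormatError(f"{path}: PLY has no face element")
    return cloud, faces


def write_cloud(cloud: PointCloud, path, format: str = "auto", binary: bool = False) -> None:
    """Write a cloud as PCD or PLY (ascii by default)."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty cloud")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pcd":
        _write_pcd(cloud, path, binary=binary)
    elif fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    else:
        raise FormatError(f"unsupported format: {fmt}")


def write_mesh(cloud: PointCloud, faces: np.ndarray, path, binary: bool = False) -> None:
    """Write a triangle mesh as PLY with a face element."""
    _write_ply(cloud, Path(path), faces=np.asarray(faces, dtype=int), binary=binary)
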