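"""Synthetic time-of-flight scenes: quadruped phantom, sensor simulator, targets.

No public scan archive exists for this kind of rig, so every pipeline input is
generated: a parametric quadruped phantom with exactly known body dimensions
standing on a ground plane, distractor clutter, calibration objects (spheres,
cuboids) at known range, and a pinhole ray-casting simulator matching the
camera geometry (60°×45° aperture, 176×132 pixels, Gaussian range noise,
sparse uniform outliers).

Frames and conventions
----------------------
The *world* frame has its origin at the camera, x right, y **down**, z
horizontal away from the camera; the ground plane is ``y = camera_height``.
The *sensor* frame is the world frame rotated by the camera pitch (downward
tilt); clouds are emitted in the sensor frame, so the pass-band filter's x/z
ranges apply directly.

Range distortion
----------------
The simulator can shorten every range by a constant per-scene factor ``k``
solving ``k = 1 / s(k · m)``, where ``m`` is the true mean sensor-range of the
target and ``s`` the configured distortion law.  This makes ``s`` exactly the
map from *measured* photographic distance to the multiplicative correction
the measurement stage must apply — the quantity the calibration procedure
estimates from scans of objects of known size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import PointCloud, RigidTransform
from .datasets import reference_measurements
from .measurement import CorrectionModel, fit_correction

logger = logging.getLogger("bovimetry")

__all__ = [
    "PhantomSpec",
    "SensorSpec",
    "PhantomModel",
    "ScanResult",
    "make_phantom",
    "simulate_tof_scan",
    "make_cattle_scene",
    "make_calibration_scene",
    "reference_distortion_model",
    "landmarks_to_sensor_frame",
    "measure_cuboid_width",
    "fit_sphere_diameter",
    "GroundPlane",
    "Ellipsoid",
    "Cylinder",
    "Sphere",
    "Box",
]


# ---------------------------------------------------------------------------
# primitives (vectorised ray intersection, world frame)
# ---------------------------------------------------------------------------

class _Primitive:
    label = "distractor"

    def intersect(self, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        raise NotImplementedError


@dataclass
class GroundPlane(_Primitive):
    y: float
    label: str = "ground"

    def intersect(self, origins, dirs):
        dy = dirs[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (self.y - origins[:, 1]) / dy
        t = np.where((dy > 1e-12) & (t > 0), t, np.inf)
        return t


@dataclass
class Sphere(_Primitive):
    center: np.ndarray
    radius: float
    label: str = "distractor"

    def intersect(self, origins, dirs):
        oc = origins - np.asarray(self.center)
        b = np.einsum("ni,ni->n", oc, dirs)
        c = np.einsum("ni,ni->n", oc, oc) - self.radius ** 2
        disc = b * b - c
        t = np.where(disc >= 0, -b - np.sqrt(np.maximum(disc, 0)), np.inf)
        return np.where(t > 0, t, np.inf)


@dataclass
class Ellipsoid(_Primitive):
    center: np.ndarray
    semiaxes: np.ndarray
    label: str = "body"

    def intersect(self, origins, dirs):
        s = np.asarray(self.semiaxes, dtype=float)
        o = (origins - np.asarray(self.center)) / s
        d = dirs / s
        a = np.einsum("ni,ni->n", d, d)
        b = np.einsum("ni,ni->n", o, d)
        c = np.einsum("ni,ni->n", o, o) - 1.0
        disc = b * b - a * c
        t = np.where(disc >= 0, (-b - np.sqrt(np.maximum(disc, 0))) / a, np.inf)
        return np.where(t > 0, t, np.inf)


@dataclass
class Cylinder(_Primitive):
    """Open capped cylinder between endpoints p0 and p1."""

    p0: np.ndarray
    p1: np.ndarray
    radius: float
    label: str = "body"

    def intersect(self, origins, dirs):
        p0 = np.asarray(self.p0, dtype=float)
        axis = np.asarray(self.p1, dtype=float) - p0
        length = np.linalg.norm(axis)
        axis = axis / length
        oc = origins - p0
        d_perp = dirs - np.outer(dirs @ axis, axis)
        o_perp = oc - np.outer(oc @ axis, axis)
        a = np.einsum("ni,ni->n", d_perp, d_perp)
        b = np.einsum("ni,ni->n", o_perp, d_perp)
        c = np.einsum("ni,ni->n", o_perp, o_perp) - self.radius ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            disc = b * b - a * c
            t = np.where((disc >= 0) & (a > 1e-14),
                         (-b - np.sqrt(np.maximum(disc, 0))) / a, np.inf)
            hit = origins + np.where(np.isfinite(t), t, 0.0)[:, None] * dirs
            h = (hit - p0) @ axis
        ok = np.isfinite(t) & (t > 0) & (h >= 0) & (h <= length)
        return np.where(ok, t, np.inf)


@dataclass
class Rotated(_Primitive):
    """A primitive rotated by R about a pivot (rays are counter-rotated)."""

    inner: _Primitive
    rotation: np.ndarray
    pivot: np.ndarray

    @property
    def label(self) -> str:  # type: ignore[override]
        return self.inner.label

    def intersect(self, origins, dirs):
        R = np.asarray(self.rotation)
        piv = np.asarray(self.pivot)
        o = (origins - piv) @ R + piv       # rotate rays into the local frame
        d = dirs @ R
        return self.inner.intersect(o, d)


@dataclass
class Box(_Primitive):
    """Axis-aligned box (slab intersection)."""

    lo: np.ndarray
    hi: np.ndarray
    label: str = "distractor"

    def intersect(self, origins, dirs):
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / dirs
        t1 = (lo - origins) * inv
        t2 = (hi - origins) * inv
        tmin = np.minimum(t1, t2).max(axis=1)
        tmax = np.maximum(t1, t2).min(axis=1)
        ok = (tmax >= tmin) & (tmax > 0)
        t = np.where(tmin > 0, tmin, tmax)
        return np.where(ok & (t > 0), t, np.inf)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Target body dimensions of the quadruped phantom (metres)."""

    withers_height: float = 1.57
    chest_depth: float = 0.65
    back_height: float = 1.56
    body_length: float = 1.59
    waist_height: float = 1.60
    leg_radius: float = 0.05
    body_radius: float = 0.22     # half-width of the torso along the range axis

    def __post_init__(self) -> None:
        vals = (self.withers_height, self.chest_depth, self.back_height,
                self.body_length, self.waist_height, self.leg_radius, self.body_radius)
        if any(v <= 0 for v in vals):
            raise ValueError("all phantom dimensions must be positive")
        checks = {
            "chest_depth < withers_height": self.chest_depth < self.withers_height,
            "back_height <= withers_height + 0.1":
                self.back_height <= self.withers_height + 0.1,
            "waist_height <= withers_height + 0.15":
                self.waist_height <= self.withers_height + 0.15,
            "body bottom clears the ground":
                self.back_height - 1.1 * self.chest_depth > 0.2,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError("inconsistent phantom spec: " + "; ".join(bad))

    def as_dict(self) -> dict[str, float]:
        return {
            "withers_height": self.withers_height,
            "chest_depth": self.chest_depth,
            "back_height": self.back_height,
            "body_length": self.body_length,
            "waist_height": self.waist_height,
        }


@dataclass
class SensorSpec:
    """Pinhole ToF camera: aperture, pixel grid, pose, noise and outliers."""

    fov_h_deg: float = 60.0
    fov_v_deg: float = 45.0
    width: int = 176
    height: int = 132
    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    range_noise_sigma: float = 0.002
    outlier_count: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fov_h_deg < 180 and 0 < self.fov_v_deg < 180):
            raise ValueError("field of view must lie in (0, 180) degrees")
        if self.width < 1 or self.height < 1:
            raise ValueError("resolution must be positive")

    @classmethod
    def tripod(cls, pitch_deg: float = 20.0, **kwargs) -> "SensorSpec":
        """Camera pitched downward by ``pitch_deg`` about the x axis."""
        pose = RigidTransform.from_axis_angle((1.0, 0.0, 0.0), -np.radians(pitch_deg))
        return cls(pose=pose, **kwargs)

    def rays(self):
        """Unit ray directions in the sensor frame, row-major pixel order."""
        tx = np.tan(np.radians(self.fov_h_deg / 2))
        ty = np.tan(np.radians(self.fov_v_deg / 2))
        u = (np.arange(self.width) + 0.5) / self.width * 2 - 1
        v = (np.arange(self.height) + 0.5) / self.height * 2 - 1
        uu, vv = np.meshgrid(u, v)
        dirs = np.column_stack([
            (uu * tx).ravel(), (vv * ty).ravel(), np.ones(self.width * self.height)
        ])
        return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


@dataclass
class PhantomModel:
    """Phantom geometry (world frame) with its exact landmark table."""

    primitives: list
    landmarks: dict[str, np.ndarray]
    spec: PhantomSpec
    ground_y: float


@dataclass
class ScanResult:
    cloud: PointCloud                 # organized, NaN for misses, sensor frame
    labels: np.ndarray                # per-pixel string labels; "none" for misses
    range_scale: float = 1.0

    def valid(self) -> tuple[PointCloud, np.ndarray]:
        """Finite points and their labels (drops organization)."""
        ok = np.isfinite(self.cloud.points).all(axis=1)
        return self.cloud.select(np.flatnonzero(ok)), self.labels[ok]


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

def make_phantom(
    spec: PhantomSpec | None = None,
    ground_y: float = 1.6,
    distance: float = 1.57,
) -> PhantomModel:
    """Build the quadruped phantom standing on ``y = ground_y`` at range ``distance``.

    The torso is three overlapping ellipsoids (shoulder, barrel, hindquarter)
    whose extreme points realise the spec's five dimensions exactly; legs and
    a neck/head add realistic structure.  The landmark table holds the seven
    measurement picks in world coordinates.
    """
    spec = spec or PhantomSpec()
    g = ground_y
    length, withers, back = spec.body_length, spec.withers_height, spec.back_height
    waist, depth, c = spec.waist_height, spec.chest_depth, spec.body_radius
    z0 = distance

    x_s, a_s, b_s = -0.28 * length, 0.22 * length, depth / 2
    x_b, a_b, b_b = 0.03 * length, 0.38 * length, 0.55 * depth
    x_h, a_h, b_h = 0.33 * length, 0.17 * length, 0.50 * depth
    shoulder = Ellipsoid((x_s, g - withers + b_s, z0), (a_s, b_s, c))
    barrel = Ellipsoid((x_b, g - back + b_b, z0), (a_b, b_b, c))
    hip = Ellipsoid((x_h, g - waist + b_h, z0), (a_h, b_h, 0.9 * c))

    # Below the brisket line the torso is slab-sided and the legs are
    # full-width slabs flush with it: a convex torso pinches to a point at the
    # belly, which would leave a depth jump between the visible flank and the
    # legs larger than the clustering tolerance and disconnect the subject
    # from its ground contact in the scan.
    brisket_y = g - (withers - depth)
    lower_torso = Box(
        (x_s - 0.6 * a_s, g - 0.75 * withers, z0 - c),
        (x_h + 0.6 * a_h, brisket_y, z0 + c),
        label="body",
    )
    # each leg slab is yawed a little so its side faces are not edge-on to
    # the sensor (grazing faces sample too sparsely and sever the scan's
    # body-to-ground connectivity)
    yaw = np.radians(12.0)
    R_yaw = np.array([
        [np.cos(yaw), 0.0, np.sin(yaw)],
        [0.0, 1.0, 0.0],
        [-np.sin(yaw), 0.0, np.cos(yaw)],
    ])
    legs = [
        Rotated(
            Box((x - spec.leg_radius, brisket_y - 0.02, z0 - c),
                (x + spec.leg_radius, g, z0 + c), label="body"),
            R_yaw, np.array([x, g, z0]),
        )
        for x in (x_s, x_h)
    ]
    head_c = np.array([-0.62 * length, g - withers + 0.15, z0])
    neck = Cylinder((x_s - 0.1 * length, g - withers + b_s, z0), head_c, 0.07)
    head = Ellipsoid(head_c, (0.12, 0.10, 0.09))

    landmarks = {
        "withers_top": np.array([x_s, g - withers, z0]),
        "chest_top": np.array([x_s, g - withers, z0]),
        "chest_bottom": np.array([x_s, g - withers + depth, z0]),
        "back_top": np.array([x_b, g - back, z0]),
        "waist_top": np.array([x_h, g - waist, z0]),
        "shoulder_point": np.array([-length / 2, g - (withers - b_s), z0]),
        "pin_bone": np.array([length / 2, g - (waist - b_h), z0]),
    }
    return PhantomModel([shoulder, barrel, hip, *legs, neck, head], landmarks, spec, g)


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

def simulate_tof_scan(
    primitives: list,
    sensor: SensorSpec | None = None,
    range_scale: float = 1.0,
) -> ScanResult:
    """Ray-cast a scene into an organized 176×132 range scan.

    Per pixel, the nearest primitive hit gives the true range; Gaussian noise
    (``range_noise_sigma``) is added along the ray, the whole range image is
    scaled by ``range_scale`` (the injected sensor distortion), and misses are
    NaN.  ``outlier_count`` randomly chosen pixels are replaced by uniform
    ranges in the working band.  Deterministic under the sensor seed.
    """
    sensor = sensor or SensorSpec()
    if not primitives:
        raise ValueError("scene must contain at least one primitive")
    dirs_sensor = sensor.rays()
    n = len(dirs_sensor)
    origins = np.broadcast_to(sensor.pose.translation, (n, 3))
    dirs_world = dirs_sensor @ sensor.pose.rotation.T
    t_all = np.stack([p.intersect(origins, dirs_world) for p in primitives])
    best = t_all.argmin(axis=0)
    t = t_all[best, np.arange(n)]
    labels = np.array([p.label for p in primitives], dtype=object)[best]
    labels = np.where(np.isfinite(t), labels, "none").astype(object)
    if np.isfinite(t).any() and np.nanmin(np.where(np.isfinite(t), t, np.nan)) < 1e-6:
        raise ValueError("sensor lies inside scene geometry")
    rng = np.random.default_rng(sensor.seed)
    t_noisy = t + rng.normal(0.0, sensor.range_noise_sigma, n)
    if sensor.outlier_count:
        pix = rng.choice(n, size=min(sensor.outlier_count, n), replace=False)
        t_noisy[pix] = rng.uniform(1.55, 2.95, len(pix)) / dirs_sensor[pix, 2]
        labels[pix] = "outlier"
    t_noisy = t_noisy * range_scale
    pts = dirs_sensor * t_noisy[:, None]
    pts[~np.isfinite(t)] = np.nan
    cloud = PointCloud(pts, width=sensor.width, height=sensor.height)
    return ScanResult(cloud, labels, range_scale)


def reference_distortion_model() -> CorrectionModel:
    """Distance-correction law implied by the published worked examples.

    Fits s(d) to the 15 (photographic distance, corrected/initial ratio)
    observations of the three reference scenes — a quadratic determined by the
    three distances.  Used both as the default injected sensor distortion and
    as a regression target for the calibration fit.
    """
    ref = reference_measurements()
    obs = list(zip(ref["distance_m"], ref["initial_m"], ref["corrected_m"]))
    return fit_correction(obs)


def _solve_range_scale(target_mean_range: float, distortion: CorrectionModel) -> float:
    """Solve k · s(k · m) = 1: the per-scene range shrink factor.

    With s positive and increasing over the working range the left side is
    strictly increasing in k, so the root is unique; bisection is used because
    plain fixed-point iteration stops contracting where s grows steeply.
    """
    m = target_mean_range
    lo, hi = 0.05, 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid * distortion.scale(mid * m) < 1.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-13:
            break
    return 0.5 * (lo + hi)


def make_cattle_scene(
    spec: PhantomSpec | None = None,
    distance: float = 1.57,
    camera_height: float = 1.6,
    pitch_deg: float = 20.0,
    distortion: CorrectionModel | None = None,
    with_distractor: bool = True,
    outlier_count: int = 80,
    range_noise_sigma: float = 0.002,
    seed: int | None = 0,
) -> tuple[ScanResult, PhantomModel, SensorSpec]:
    """Standard study scene: phantom on the floor, clutter, noise, distortion.

    Returns the organized scan (sensor frame), the phantom (with world-frame
    landmarks), and the sensor used.  When ``distortion`` is given, ranges are
    shrunk by the per-scene factor solving the fixed point documented in the
    module header, so downstream calibration can undo it exactly.
    """
    spec = spec or PhantomSpec()
    sensor = SensorSpec.tripod(
        pitch_deg=pitch_deg, range_noise_sigma=range_noise_sigma,
        outlier_count=outlier_count, seed=seed,
    )
    clean_sensor = SensorSpec.tripod(pitch_deg=pitch_deg, range_noise_sigma=0.0, seed=0)

    def build(z0: float):
        phantom = make_phantom(spec, ground_y=camera_height, distance=z0)
        scene = list(phantom.primitives) + [GroundPlane(camera_height)]
        if with_distractor:
            # floating block beyond the head, clear of ground and body
            scene.append(Box((-1.24, camera_height - 1.25, 2.2),
                             (-1.12, camera_height - 0.85, 2.45)))
        return phantom, scene

    def pipeline_distance(scene, k: float) -> tuple[float, float]:
        """Photographic distance exactly as the measurement stage computes it.

        Runs the fused filter and target segmentation on a noiseless scan at
        distortion factor ``k`` and returns (mean z of the segmented target,
        fraction of body pixels inside the pass band).
        """
        from .filters import FilterParams, fused_filter
        from .segmentation import ClusterParams, RansacParams, segment_target

        res = simulate_tof_scan(scene, clean_sensor, range_scale=k)
        cl, lab = res.valid()
        body_pts = cl.points[lab == "body"]
        keep = (
            (body_pts[:, 0] > -1.25) & (body_pts[:, 0] < 1.0)
            & (body_pts[:, 2] > 1.5) & (body_pts[:, 2] < 3.0)
        )
        target, _ = segment_target(
            fused_filter(cl, FilterParams()), ClusterParams(), RansacParams(seed=0)
        )
        return float(target.points[:, 2].mean()), float(keep.mean())

    # Place the body so its *measured* photographic distance — the quantity
    # the pipeline reports, on the sensor's (distorted) range scale — comes as
    # close as the working band allows to the requested one, and solve the
    # distortion factor k = 1/s(d_measured) against that same observable.
    # The subject must sit (almost) wholly inside the band: a partial cut can
    # slice the torso in two and break segmentation, so placement first finds
    # the nearest fully-in-band position and only then moves deeper if the
    # requested distance asks for it.
    z0, k = distance, 1.0
    d_meas = distance
    for _ in range(20):
        phantom, scene = build(z0)
        d_meas, frac = pipeline_distance(scene, k)
        if distortion is not None:
            k = 1.0 / distortion.scale(d_meas)
        if frac < 0.95:
            z0 += 0.05                      # push the subject deeper into the band
            continue
        err = distance - d_meas
        if err < 2e-3:                       # at or beyond the nearest feasible range
            break
        z0 += 0.8 * err / k
    if d_meas - distance > 2e-3:
        logger.info(
            "subject placed at photographic distance %.3f m: %.3f m is closer "
            "than the pass band allows for a full view", d_meas, distance,
        )
    scan = simulate_tof_scan(scene, sensor, range_scale=k)
    return scan, phantom, sensor


def landmarks_to_sensor_frame(
    phantom: PhantomModel, sensor: SensorSpec, range_scale: float = 1.0
) -> dict[str, np.ndarray]:
    """Phantom landmark picks as they appear in the (distorted) scan frame."""
    inv = sensor.pose.inverse()
    return {k: inv.apply(v) * range_scale for k, v in phantom.landmarks.items()}


# ---------------------------------------------------------------------------
# calibration scenes
# ---------------------------------------------------------------------------

def make_calibration_scene(
    kind: str,
    size: float | tuple[float, float, float],
    distance: float,
    sensor: SensorSpec | None = None,
    distortion: CorrectionModel | None = None,
    center_offset: tuple[float, float] = (0.0, 0.0),
) -> tuple[ScanResult, float]:
    """Scan a calibration object of known size at a known range.

    ``kind`` is ``"sphere"`` (``size`` = radius; true dimension = diameter) or
    ``"cuboid"`` (``size`` = (w, h, l); true dimension = width w).  The object
    sits near the optical axis of a level (pitch 0) camera;
    ``center_offset`` shifts it laterally (x, y) so repeated scans sample
    different pixel phases, as hand-placed objects do.  Returns the scan and
    the true dimension; the injected distortion factor is recorded on the
    scan so tests can verify recovery.
    """
    sensor = sensor or SensorSpec(range_noise_sigma=0.002, seed=0)
    ox, oy = center_offset
    if kind == "sphere":
        obj = Sphere((ox, oy, distance), float(size), label="target")
        true_dim = 2.0 * float(size)
    elif kind == "cuboid":
        w, h, length = size
        lo = np.array([ox - w / 2, oy - h / 2, distance - length / 2])
        hi = np.array([ox + w / 2, oy + h / 2, distance + length / 2])
        obj = Box(lo, hi, label="target")
        true_dim = float(w)
    else:
        raise ValueError(f"unknown calibration object kind: {kind}")
    k = 1.0
    if distortion is not None:
        clean = simulate_tof_scan([obj], SensorSpec(
            pose=sensor.pose, range_noise_sigma=0.0, seed=0))
        cl, lab = clean.valid()
        if len(cl) == 0:
            raise ValueError("calibration object is outside the sensor frustum")
        m = float(cl.points[lab == "target", 2].mean())
        k = _solve_range_scale(m, distortion)
    scan = simulate_tof_scan([obj], sensor, range_scale=k)
    if not np.isfinite(scan.cloud.points).any():
        raise ValueError("calibration object is outside the sensor frustum")
    return scan, true_dim


def calibration_observations(
    distortion: CorrectionModel | None,
    distances=(1.7, 1.85, 2.0, 2.15, 2.3, 2.45, 2.6, 2.75),
    cuboid=(0.5, 0.4, 0.3),
    sphere_radius: float = 0.25,
    noise_sigma: float = 0.002,
    seed: int = 0,
) -> list[tuple[float, float, float]]:
    """Scan cuboids and spheres over a range of distances for correction fitting.

    For every distance one cuboid and one sphere are scanned with small
    seeded lateral placement offsets (so pixel phases vary) and measured;
    returns (measured photographic distance, raw dimension, true dimension)
    triples ready for :func:`bovimetry.measurement.fit_correction`.
    """
    rng = np.random.default_rng(seed)
    obs = []
    for d in distances:
        for kind, size, measure in (
            ("cuboid", cuboid, None),
            ("sphere", sphere_radius, None),
        ):
            sensor = SensorSpec(
                range_noise_sigma=noise_sigma, seed=int(rng.integers(2**31))
            )
            offset = tuple(rng.uniform(-0.02, 0.02, 2))
            scan, true_dim = make_calibration_scene(
                kind, size, d, sensor, distortion=distortion, center_offset=offset
            )
            cloud, labels = scan.valid()
            target = cloud.select(np.flatnonzero(labels == "target"))
            raw = (
                measure_cuboid_width(target, sensor)
                if kind == "cuboid"
                else fit_sphere_diameter(target)
            )
            obs.append((float(target.points[:, 2].mean()), raw, true_dim))
    return obs


def measure_cuboid_width(cloud: PointCloud, sensor: SensorSpec | None = None) -> float:
    """Width of a camera-facing cuboid scan: x extent of its front face.

    Scan points are pixel-ray samples, so the raw max − min extent
    understates the physical edge-to-edge width by about one pixel footprint;
    the estimate adds that footprint back (computed from the sensor's
    horizontal angular pitch at the face's range).
    """
    sensor = sensor or SensorSpec()
    pts = cloud.points[np.isfinite(cloud.points).all(axis=1)]
    if len(pts) == 0:
        raise ValueError("empty scan")
    front = pts[pts[:, 2] <= pts[:, 2].min() + 0.01]
    pitch = 2 * np.tan(np.radians(sensor.fov_h_deg / 2)) / sensor.width
    return float(front[:, 0].max() - front[:, 0].min() + pitch * front[:, 2].mean())


def fit_sphere_diameter(cloud: PointCloud) -> float:
    """Algebraic least-squares sphere fit; returns the fitted diameter."""
    pts = cloud.points[np.isfinite(cloud.points).all(axis=1)]
    if len(pts) < 4:
        raise ValueError("need at least 4 points to fit a sphere")
    A = np.column_stack([2 * pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = np.sqrt(sol[3] + center @ center)
    return float(2 * radius)
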