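"""Shared fixtures: synthetic scenes, calibration model, feature library.

Scene generation dominates test runtime, so scans and derived artifacts are
built once per session and reused read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from bovimetry.features import build_feature_library
from bovimetry.filters import FilterParams, fused_filter
from bovimetry.measurement import fit_correction
from bovimetry.segmentation import ClusterParams, RansacParams, segment_target
from bovimetry.synthetic_scene import (
    calibration_observations,
    make_cattle_scene,
    reference_distortion_model,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def distortion():
    return reference_distortion_model()


@pytest.fixture(scope="session")
def clean_scene():
    """Noisy but undistorted default scene: (ScanResult, PhantomModel, SensorSpec)."""
    return make_cattle_scene(seed=1)


@pytest.fixture(scope="session")
def distorted_scene(distortion):
    """Default scene with the reference range distortion injected."""
    return make_cattle_scene(seed=7, distortion=distortion)


@pytest.fixture(scope="session")
def correction_model(distortion):
    """Correction fit from synthetic cuboid/sphere calibration scans."""
    return fit_correction(calibration_observations(distortion, seed=0))


def _segment(scan):
    cloud, labels = scan.valid()
    body, plane = segment_target(
        fused_filter(cloud, FilterParams()), ClusterParams(), RansacParams(seed=0)
    )
    return cloud, labels, body, plane


@pytest.fixture(scope="session")
def clean_segmented(clean_scene):
    """(valid cloud, labels, segmented body, ground plane) for the clean scene."""
    return _segment(clean_scene[0])


@pytest.fixture(scope="session")
def distorted_segmented(distorted_scene):
    return _segment(distorted_scene[0])


@pytest.fixture(scope="session")
def dense_bodies():
    """Two dense, independently sampled body scans for registration tests.

    A doubled-resolution sensor gives ~5 mm surface sampling so closest-point
    residuals reflect registration quality rather than sampling pitch.
    """
    from bovimetry.synthetic_scene import GroundPlane, SensorSpec, make_phantom, simulate_tof_scan

    phantom = make_phantom(ground_y=1.6, distance=1.7)
    scene = list(phantom.primitives) + [GroundPlane(1.6)]
    bodies = []
    for seed in (1, 2):
        sensor = SensorSpec.tripod(pitch_deg=20.0, range_noise_sigma=0.002, seed=seed)
        sensor.width, sensor.height = 352, 264
        cloud, labels = simulate_tof_scan(scene, sensor).valid()
        bodies.append(cloud.points[labels == "body"])
    return bodies


@pytest.fixture(scope="session")
def feature_library(distortion):
    """VFH library from two same-rig scans of the phantom."""
    bodies, labels = [], []
    for seed in (99, 100):
        scan, _, _ = make_cattle_scene(seed=seed, distortion=distortion)
        _, _, body, _ = (*_segment(scan),)
        bodies.append(body)
        labels.append(f"cattle-{seed}")
    return build_feature_library(bodies, labels=labels)
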