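"""Projection-distance measurement, distance correction, deviation arithmetic."""

import numpy as np
import pytest

from bovimetry.core_io import RigidTransform
from bovimetry.datasets import reference_measurements, reference_scene_distances
from bovimetry.measurement import (
    DIMENSION_NAMES,
    BodyDimensions,
    BodyPicks,
    CorrectionModel,
    apply_correction,
    compute_body_dimensions,
    deviation_report,
    fit_correction,
    measure_height,
    measure_length,
)
from bovimetry.segmentation import PlaneModel


GROUND = PlaneModel([0, 0, 1.0], 0.0)     # plane z = 0


def make_picks(**heights):
    """Picks over the z=0 ground with given heights and a 1.6 m body axis."""
    h = {
        "withers": 1.57, "chest_top": 1.57, "chest_bottom": 0.92,
        "back": 1.56, "waist": 1.60, "shoulder": 0.9, "pin": 0.95,
    }
    h.update(heights)
    return BodyPicks({
        "withers_top": [0.0, 0, h["withers"]],
        "chest_top": [0.1, 0, h["chest_top"]],
        "chest_bottom": [0.1, 0, h["chest_bottom"]],
        "back_top": [0.5, 0, h["back"]],
        "waist_top": [1.0, 0, h["waist"]],
        "shoulder_point": [-0.2, 0, h["shoulder"]],
        "pin_bone": [1.39, 0, h["pin"]],
    }, photographic_distance=1.6)


class TestProjectionDistances:
    def test_height_above_axis_aligned_plane(self):
        assert measure_height([0, 0, 1.3], GROUND) == pytest.approx(1.3)

    def test_height_on_tilted_plane_by_construction(self, rng):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        base = rng.normal(size=3)
        plane = PlaneModel(normal, -normal @ base)
        point = base + 1.5 * normal
        assert measure_height(point, plane) == pytest.approx(1.5)

    def test_height_invariant_under_joint_rigid_motion(self, rng):
        plane = PlaneModel([0, 0, 1.0], -0.2)
        p = np.array([0.3, -0.1, 1.0])
        T = RigidTransform.from_axis_angle(rng.normal(size=3), 0.8, rng.normal(size=3))
        n2 = T.rotation @ plane.normal
        base = plane.project(p)[0]
        plane2 = PlaneModel(n2, -n2 @ T.apply(base))
        assert measure_height(T.apply(p), plane2) == pytest.approx(
            measure_height(p, plane), abs=1e-9
        )

    def test_vertical_separation_projects_to_zero_length(self):
        with pytest.warns(UserWarning):
            assert measure_length([0, 0, 0.5], [0, 0, 1.5], GROUND) == 0.0

    def test_horizontal_length(self):
        assert measure_length([0, 0, 0], [1.6, 0, 0], GROUND) == pytest.approx(1.6)


class TestCorrectionModel:
    def test_noiseless_linear_law_recovered_exactly(self):
        obs = [(d, 1.0, 1.05 + 0.08 * d) for d in (1.5, 2.0, 2.5, 2.0)]
        model = fit_correction(obs)
        for d in (1.5, 1.8, 2.2, 2.5):
            assert model.scale(d) == pytest.approx(1.05 + 0.08 * d, abs=1e-9)
        assert model.residual_rms < 1e-12

    def test_single_distance_rejected(self):
        with pytest.raises(ValueError, match="distances"):
            fit_correction([(2.0, 1.0, 1.1)] * 5)

    def test_published_scene_ratio_reproduces_corrected_value(self):
        ref = reference_measurements()
        t1 = ref[ref.scene == "Q0521"]
        ratio = (t1.corrected_m / t1.initial_m).mean()
        model = CorrectionModel([ratio], calibrated_range=(1.5, 1.7))
        corrected = apply_correction(model, 1.41508, 1.57047)
        assert corrected == pytest.approx(1.58461, abs=2e-5)

    def test_correction_monotone_in_raw(self):
        model = CorrectionModel([0.05, 1.0], calibrated_range=(1.0, 3.0))
        vals = [apply_correction(model, r, 2.0) for r in (0.5, 1.0, 1.5)]
        assert vals == sorted(vals)

    def test_warns_outside_calibrated_range(self):
        model = CorrectionModel.identity()
        with pytest.warns(UserWarning, match="outside"):
            apply_correction(model, 1.0, 99.0)

    def test_non_positive_raw_rejected(self):
        with pytest.raises(ValueError):
            apply_correction(CorrectionModel.identity(), 0.0, 2.0)

    def test_round_trip_serialization(self, tmp_path):
        model = CorrectionModel([0.1, -0.2, 1.5], (1.2, 2.8), 0.003)
        model.save(tmp_path / "c.json")
        back = CorrectionModel.load(tmp_path / "c.json")
        np.testing.assert_array_equal(back.coeffs, model.coeffs)
        assert back.calibrated_range == model.calibrated_range

    def test_noisy_cuboid_calibration_recovers_law_within_1pct(self, distortion):
        from bovimetry.measurement import fit_correction
        from bovimetry.synthetic_scene import calibration_observations

        obs = calibration_observations(distortion, seed=3)
        model = fit_correction(obs)
        d_obs = np.array([o[0] for o in obs])
        lo, hi = np.quantile(d_obs, [0.15, 0.85])  # calibrated interior
        for d in np.linspace(lo, hi, 8):
            assert model.scale(d) == pytest.approx(distortion.scale(d), rel=0.01)


class TestBodyDimensions:
    def test_heights_and_length_from_picks(self):
        dims = compute_body_dimensions(make_picks(), GROUND)
        assert dims.raw["withers_height"] == pytest.approx(1.57)
        assert dims.raw["chest_depth"] == pytest.approx(0.65)
        assert dims.raw["back_height"] == pytest.approx(1.56)
        assert dims.raw["waist_height"] == pytest.approx(1.60)
        assert dims.raw["body_length"] == pytest.approx(1.59)

    def test_correction_ratio_uniform_across_dimensions(self):
        model = CorrectionModel([0.05, 1.0], calibrated_range=(1.0, 3.0))
        dims = compute_body_dimensions(make_picks(), GROUND, model)
        ratios = {k: dims.corrected[k] / dims.raw[k] for k in DIMENSION_NAMES}
        spread = max(ratios.values()) - min(ratios.values())
        assert spread < 1e-12

    def test_missing_pick_is_named(self):
        with pytest.raises(ValueError, match="pin_bone"):
            BodyPicks({n: [0, 0, 0] for n in
                       ("withers_top", "chest_top", "chest_bottom", "back_top",
                        "waist_top", "shoulder_point")}, 1.6)

    def test_ground_level_picks_rejected_as_nonpositive(self):
        picks = make_picks(withers=0.0)
        with pytest.raises(ValueError, match="positive"):
            compute_body_dimensions(picks, GROUND)


class TestDeviationReport:
    def test_published_back_height_deviation(self):
        measured = BodyDimensions(
            raw={n: 1.0 for n in DIMENSION_NAMES},
            corrected={**{n: 1.0 for n in DIMENSION_NAMES}, "back_height": 1.55236},
            photographic_distance=1.57,
        )
        rep = deviation_report(measured, {**{n: 1.0 for n in DIMENSION_NAMES},
                                          "back_height": 1.55600})
        row = rep.table.set_index("dimension").loc["back_height"]
        assert round(row.final_dev_pct, 2) == 0.23

    def test_published_initial_deviation(self):
        dev = 100 * abs(1.27672 - 1.53400) / 1.53400
        assert round(dev, 2) == 16.77

    def test_exact_match_gives_zero(self):
        vals = {n: 1.2 for n in DIMENSION_NAMES}
        measured = BodyDimensions(dict(vals), dict(vals), 1.6)
        rep = deviation_report(measured, vals)
        assert rep.max_final_deviation == 0.0

    def test_zero_reference_rejected(self):
        vals = {n: 1.2 for n in DIMENSION_NAMES}
        measured = BodyDimensions(dict(vals), dict(vals), 1.6)
        with pytest.raises(ValueError):
            deviation_report(measured, {**vals, "back_height": 0.0})

    def test_all_thirty_published_deviations_reproduced(self):
        ref = reference_measurements()
        for _, row in ref.iterrows():
            initial = 100 * abs(row.initial_m - row.manual_m) / row.manual_m
            final = 100 * abs(row.corrected_m - row.manual_m) / row.manual_m
            # agreement to +/-0.01 percentage points at the printed precision
            assert abs(round(initial, 2) - row.initial_dev_pct) <= 0.01 + 1e-9
            assert abs(round(final, 2) - row.final_dev_pct) <= 0.01 + 1e-9

    def test_per_scene_ratio_constancy(self):
        ref = reference_measurements()
        for scene, grp in ref.groupby("scene"):
            r = grp.corrected_m / grp.initial_m
            assert (r.max() - r.min()) / r.mean() < 1e-3

    def test_scene_ratio_fit_reproduces_corrected_values(self):
        ref = reference_measurements()
        obs = list(zip(ref.distance_m, ref.initial_m, ref.corrected_m))
        model = fit_correction(obs)
        for _, row in ref.iterrows():
            pred = apply_correction(model, row.initial_m, row.distance_m)
            assert abs(pred - row.corrected_m) / row.corrected_m < 1e-3

    def test_reference_distances_match_tables(self):
        d = reference_scene_distances()
        assert d == {"Q0521": 1.57047, "Q0145": 1.78572, "Q0159": 1.54938}
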