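"""Parametric cochlea surfaces, landmarks, and the synthetic implant generator."""

import numpy as np
import pytest

import scalafit as sf
from scalafit.errors import (
    CoverageError,
    ParameterError,
    TranslocationSpecError,
)
from scalafit.geometry import analytic_landmarks, spiral_height, spiral_radius

from conftest import random_similarity


class TestSpiralSurface:
    def test_angular_span_equals_turns(self, template):
        assert template.angular_span == (0.0, 2.75 * 360.0)

    def test_height_rise_over_first_turn_matches_h360(self, default_params):
        z0 = spiral_height(default_params, 0.0)
        z360 = spiral_height(default_params, 2 * np.pi)
        assert z360 - z0 == pytest.approx(2.8, abs=1e-12)

    def test_height_profile_monotone(self, default_params):
        th = np.linspace(0, default_params.theta_max, 500)
        z = spiral_height(default_params, th)
        assert np.all(np.diff(z) >= 0)

    def test_midline_angle_strictly_increasing(self, template):
        mid = np.abs(template.width_frac) < 1e-12
        assert np.all(np.diff(template.angular_coord[mid]) > 0)

    def test_left_is_mirror_image_of_right(self, default_params):
        import dataclasses

        right = sf.make_membrane_surface(default_params, 10.0)
        left = sf.make_membrane_surface(
            dataclasses.replace(default_params, side="left"), 10.0)
        # best-fit orthogonal map between identically-ordered vertex sets
        x = right.vertices - right.vertices.mean(0)
        y = left.vertices - left.vertices.mean(0)
        u, _, vt = np.linalg.svd(y.T @ x)
        assert np.linalg.det(u @ vt) == pytest.approx(-1.0, abs=1e-9)
        # and no proper rotation achieves a (near) zero residual
        t = sf.fit_landmark_transform(right.vertices[::7], left.vertices[::7],
                                      allow_scale=False)
        assert t.rms_residual > 0.5

    def test_mirror_template_round_trip(self, coarse_template):
        back = sf.mirror_template(sf.mirror_template(coarse_template))
        assert np.allclose(back.vertices, coarse_template.vertices)
        assert back.side == coarse_template.side

    def test_normals_lean_toward_scala_vestibuli(self, template):
        v, f = template.vertices, template.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        assert np.median(fn[:, 2] / np.linalg.norm(fn, axis=1)) > 0.5

    @pytest.mark.parametrize("bad", [
        dict(basal_radius_a=-1.0), dict(decay_b=0.0), dict(turns=3.5),
        dict(height_h360=6.0), dict(duct_width=np.nan),
    ])
    def test_invalid_parameters_rejected(self, bad):
        base = dict(basal_radius_a=5.8, decay_b=0.25, turns=2.75,
                    height_h360=2.8, total_height=5.25, duct_width=0.8)
        base.update(bad)
        with pytest.raises(ParameterError):
            sf.SpiralParams(**base)

    def test_dimension_solve_round_trips_measurements(self):
        for a, b, h, turns in [(9.1, 6.8, 2.8, 2.75), (8.5, 6.2, 2.4, 2.25),
                               (9.6, 7.5, 3.3, 3.0)]:
            p = sf.params_from_dimensions(a, b, h, turns=turns)
            lm = analytic_landmarks(p)
            dims = sf.measure_dimensions(lm, h)
            assert dims.a == pytest.approx(a, abs=1e-9)
            assert dims.b == pytest.approx(b, abs=1e-9)


class TestLandmarks:
    def test_lateral_wall_matches_closed_form(self, default_params, template):
        lm = sf.extract_landmarks(template)
        p = default_params
        expected_r = spiral_radius(p, np.pi) + p.duct_width / 2
        got_r = np.hypot(lm.lw180[0], lm.lw180[1])
        # discretization: vertex nearest 180 deg is within half an angular step
        assert got_r == pytest.approx(expected_r, abs=0.05)
        assert np.allclose(lm.rw_center, analytic_landmarks(p).rw_center,
                           atol=0.05)

    def test_cropped_template_loses_round_window(self, template):
        cropped = sf.crop_by_angle(template, 90.0, 540.0)
        with pytest.raises(CoverageError):
            sf.extract_landmarks(cropped)

    def test_equivariance_under_rigid_motion(self, coarse_template):
        rng = np.random.default_rng(3)
        t = random_similarity(rng, scale_range=(1.0, 1.0))
        moved = coarse_template.transformed(t)
        got = sf.extract_landmarks(moved).as_array()
        expected = t.apply(sf.extract_landmarks(coarse_template).as_array())
        assert np.allclose(got, expected, atol=1e-9)

    def test_collinear_landmarks_rejected(self):
        from scalafit.errors import DegenerateGeometryError

        with pytest.raises(DegenerateGeometryError):
            sf.CochlearLandmarks([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])


class TestSyntheticArrays:
    def test_clean_insertion_truth_all_st(self, template):
        _, truth = sf.synth_electrode_array(template, "midscala_like",
                                            sf.TranslocationSpec("none"))
        assert truth == ["ST"] * 16

    def test_proximal_crossing_truth(self, template):
        arr, truth = sf.synth_electrode_array(
            template, "midscala_like",
            sf.TranslocationSpec("proximal_crossing", 180.0))
        # every electrode apical of the crossing is scala vestibuli
        call = sf.classify_array(arr, template, sf.SimilarityTransform.identity())
        for c, t in zip(call.calls, truth):
            assert (t == "SV") == (c.angle_deg > 180.0)

    def test_distal_bending_truth_intermediate(self, template):
        _, truth = sf.synth_electrode_array(
            template, "evo_like", sf.TranslocationSpec("distal_bending", 310.0))
        assert "INT" in truth and "SV" not in truth
        assert truth[0] == "ST"

    def test_simulator_consistent_with_classifier(self, template):
        # clearance above the contact radius puts the whole contact under
        arr, _ = sf.synth_electrode_array(template, "evo_like",
                                          sf.TranslocationSpec("none"))
        call = sf.classify_array(arr, template, sf.SimilarityTransform.identity())
        assert all(c.fraction_under == 1.0 for c in call.calls)
        assert all(c.signed_distance <= -arr.contact_diameter / 2
                   for c in call.calls)

    def test_determinism(self, template):
        spec = sf.TranslocationSpec("proximal_crossing", 180.0)
        a1, t1 = sf.synth_electrode_array(template, "evo_like", spec, seed=9,
                                          center_jitter=0.02)
        a2, t2 = sf.synth_electrode_array(template, "evo_like", spec, seed=9,
                                          center_jitter=0.02)
        assert np.array_equal(a1.centers, a2.centers) and t1 == t2

    def test_onset_outside_extent_rejected(self, template):
        with pytest.raises(TranslocationSpecError):
            sf.synth_electrode_array(
                template, "midscala_like",
                sf.TranslocationSpec("distal_bending", 440.0), depth_angle=420.0)

    def test_depth_beyond_template_rejected(self, template):
        with pytest.raises(ParameterError):
            sf.synth_electrode_array(template, "evo_like",
                                     sf.TranslocationSpec("none"),
                                     depth_angle=1100.0)


class TestCohort:
    def test_zero_noise_landmarks_equal_extraction(self):
        s = sf.CohortSettings(landmark_sigma=0.0, randomize_pose=False)
        case = sf.synth_case(5, s)
        expected = sf.extract_landmarks(case.template_truth).as_array()
        assert np.array_equal(case.landmarks_noisy.as_array(), expected)

    def test_seeded_determinism_bit_for_bit(self):
        c1, c2 = (sf.synth_cohort(3, seed=21)[1] for _ in range(2))
        assert np.array_equal(c1.array.centers, c2.array.centers)
        assert np.array_equal(c1.template_truth.vertices,
                              c2.template_truth.vertices)
        assert c1.truth_calls == c2.truth_calls

    def test_empty_cohort_rejected(self):
        with pytest.raises(ParameterError):
            sf.synth_cohort(0)

    def test_dimension_sampler_matches_population(self):
        from scalafit.studies import _sample_dimensions

        rng = np.random.default_rng(17)
        s = sf.CohortSettings()
        draws = np.array([_sample_dimensions(rng, s) for _ in range(2000)])
        for j, (mu, sd) in enumerate([(9.1, 0.30), (6.8, 0.32), (2.8, 0.21)]):
            se = sd / np.sqrt(len(draws))
            assert abs(draws[:, j].mean() - mu) < 3 * se

    def test_cohort_carries_consistent_truth(self):
        for case in sf.synth_cohort(4, seed=2):
            assert len(case.truth_calls) == case.array.n_electrodes
            assert case.array.n_electrodes in (16, 20)
            if case.translocation.pattern == "none":
                assert set(case.truth_calls) == {"ST"}
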