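"""Signed distances, spherical-cap fractions, and scalar category calls."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import scalafit as sf
from scalafit.errors import ParameterError
from scalafit.meshquery import MeshQuery

from conftest import random_similarity


class TestFractionUnder:
    def test_spherical_cap_analytics(self):
        r = 0.25
        assert sf.fraction_under(0.0, r) == 0.5
        assert sf.fraction_under(-r, r) == 1.0
        assert sf.fraction_under(+r, r) == 0.0
        assert sf.fraction_under(r / 2, r) == pytest.approx(5 / 32, abs=1e-15)
        assert sf.fraction_under(-5 * r, r) == 1.0
        assert sf.fraction_under(5 * r, r) == 0.0

    @given(st.floats(-0.24, 0.24), st.floats(-0.24, 0.24))
    def test_strictly_decreasing_inside_contact(self, d1, d2):
        if abs(d1 - d2) < 1e-9:
            return
        lo, hi = sorted([d1, d2])
        assert sf.fraction_under(lo, 0.25) > sf.fraction_under(hi, 0.25)

    def test_bad_radius_rejected(self):
        with pytest.raises(ParameterError):
            sf.fraction_under(0.0, 0.0)


class TestClassifyElectrode:
    @pytest.mark.parametrize("fraction,category", [
        (0.50, "ST"), (0.10, "INT"), (0.0999, "SV"),
        (1.0, "ST"), (0.0, "SV"), (0.49999, "INT"),
    ])
    def test_threshold_boundaries(self, fraction, category):
        assert sf.classify_electrode(fraction) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            sf.classify_electrode(1.5)


class TestSignedDistance:
    def test_point_on_surface_is_zero(self, coarse_template):
        p = coarse_template.vertices[coarse_template.n_vertices // 2]
        d, _, _ = sf.signed_distance_to_membrane(p, coarse_template)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_normal_displacement_signed(self, coarse_template):
        v, f = coarse_template.vertices, coarse_template.faces
        face = f[len(f) // 2]
        centroid = v[face].mean(axis=0)
        n = np.cross(v[face[1]] - v[face[0]], v[face[2]] - v[face[0]])
        n /= np.linalg.norm(n)
        for sign in (+1, -1):
            d, _, _ = sf.signed_distance_to_membrane(centroid + sign * 0.5 * n,
                                                     coarse_template)
            assert d == pytest.approx(sign * 0.5, abs=1e-9)

    def test_matches_per_triangle_brute_force(self, coarse_template):
        import trimesh

        rng = np.random.default_rng(2)
        pts = rng.uniform(-7, 7, (25, 3))
        signed, _, _ = sf.signed_distance_to_membrane(pts, coarse_template)
        tri = coarse_template.vertices[coarse_template.faces]
        for p, s in zip(pts, signed):
            cp = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
            brute = np.linalg.norm(cp - p, axis=1).min()
            assert abs(s) == pytest.approx(brute, abs=1e-9)

    def test_angle_reported_from_nearest_point(self, template):
        from scalafit.geometry import _midline, _surface_normal

        p = template.spiral_params
        th = np.deg2rad(200.0)
        point = _midline(p, th)[0] - 0.4 * _surface_normal(p, th)[0]
        _, angle, _ = sf.signed_distance_to_membrane(point, template)
        assert angle == pytest.approx(200.0, abs=3.0)


class TestClassifyArray:
    def test_rigid_motion_invariance(self, coarse_template):
        rng = np.random.default_rng(6)
        arr, _ = sf.synth_electrode_array(coarse_template, "evo_like",
                                          sf.TranslocationSpec("distal_bending", 320.0))
        base = sf.classify_array(arr, coarse_template,
                                 sf.SimilarityTransform.identity())
        pose = random_similarity(rng, scale_range=(1.0, 1.0))
        moved = sf.classify_array(arr.transformed(pose), coarse_template, pose)
        assert base.categories() == moved.categories()
        assert np.allclose([c.signed_distance for c in base.calls],
                           [c.signed_distance for c in moved.calls], atol=1e-9)

    def test_zero_noise_proximal_case_end_to_end(self):
        s = sf.CohortSettings(landmark_sigma=0.0)
        case = sf.synth_case(101, s, pattern="proximal_crossing",
                             model_name="midscala_like")
        t = sf.fit_landmark_transform(case.template_truth.landmarks,
                                      case.landmarks_noisy)
        call = sf.classify_array(case.array, case.template_truth, t)
        assert call.categories() == case.truth_calls
        assert call.translocated
        spacing = 420.0 / 15
        assert abs(call.first_sv_angle - 180.0) <= spacing

    def test_intermediate_calls_touch_the_membrane(self, coarse_template):
        arr, truth = sf.synth_electrode_array(
            coarse_template, "evo_like", sf.TranslocationSpec("distal_bending", 310.0))
        call = sf.classify_array(arr, coarse_template,
                                 sf.SimilarityTransform.identity())
        ints = [c for c in call.calls if c.category == "INT"]
        assert ints
        for c in ints:
            assert abs(c.signed_distance) < arr.contact_diameter / 2

    def test_basal_electrodes_flagged_outside_window(self, template):
        arr, _ = sf.synth_electrode_array(template, "midscala_like",
                                          sf.TranslocationSpec("none"))
        call = sf.classify_array(arr, template, sf.SimilarityTransform.identity())
        flagged = [c.edge_extrapolated for c in call.calls if c.angle_deg < 90]
        assert flagged and all(flagged)

    def test_boundary_projection_flagged(self, coarse_template):
        apex = coarse_template.vertices[np.argmax(coarse_template.angular_coord)]
        _, _, edge = sf.signed_distance_to_membrane(apex + [0.5, 0.5, 0.5],
                                                    coarse_template)
        assert edge

    def test_chord_method_available(self, coarse_template):
        arr, _ = sf.synth_electrode_array(coarse_template, "evo_like",
                                          sf.TranslocationSpec("none"))
        call = sf.classify_array(arr, coarse_template,
                                 sf.SimilarityTransform.identity(),
                                 method="chord")
        assert all(c.category == "ST" for c in call.calls)


class TestMeshQueryInternals:
    def test_boundary_edge_detection(self, coarse_template):
        q = MeshQuery(coarse_template.vertices, coarse_template.faces)
        # a ribbon has a boundary loop; every boundary edge belongs to one face
        assert len(q._boundary_edges) > 0
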