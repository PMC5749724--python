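"""Geometric constructions and Cardan-angle extraction.

The chord function is checked against an independent closed-form
two-circle-intersection oracle; the Cardan composition against scipy's
rotation machinery; and the frame orchestrator against constructed
poses with known answers.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import cgmkin as ck
from cgmkin.cgm_core import SegmentFrame, cardan_angles, compose_cardan
from cgmkin.errors import ConfigurationError, GeometryError

from conftest import random_rotation


def chord_oracle(P, L, W, delta):
    """Closed-form two-circle intersection in the (P, L, W) plane:
    |JC - L| = delta and |JC - P| = sqrt(d^2 - delta^2), on the side of
    the P-L line opposite W."""
    P, L, W = (np.asarray(v, dtype=float) for v in (P, L, W))
    d = np.linalg.norm(P - L)
    e1 = (P - L) / d
    w_perp = (W - L) - ((W - L) @ e1) * e1
    e2 = w_perp / np.linalg.norm(w_perp)
    a = delta**2 / d            # along L->P
    h = math.sqrt(delta**2 - a**2)
    return L + a * e1 - h * e2  # opposite side from W


def valid_chord_configs(rng, n):
    out = []
    while len(out) < n:
        P, L, W = rng.normal(scale=300.0, size=(3, 3))
        d = np.linalg.norm(P - L)
        if d < 50:
            continue
        n_vec = np.cross(W - L, P - L)
        if np.linalg.norm(n_vec) < 1e-3 * d * np.linalg.norm(W - L):
            continue
        delta = rng.uniform(0.05, 0.95) * d
        out.append((P, L, W, delta))
    return out


class TestChord:
    def test_worked_example(self):
        jc = ck.chord_joint_center((0, 0, 10), (0, 0, 0), (5, 0, 5), 6.0)
        assert np.allclose(jc, [-4.8, 0.0, 3.6], atol=1e-12)

    def test_matches_circle_intersection_oracle(self):
        rng = np.random.default_rng(42)
        for P, L, W, delta in valid_chord_configs(rng, 200):
            jc = ck.chord_joint_center(P, L, W, delta)
            d = np.linalg.norm(P - L)
            assert np.linalg.norm(jc - chord_oracle(P, L, W, delta)) < 1e-9 * d
            assert abs(np.linalg.norm(jc - L) - delta) < 1e-9 * d
            assert abs((jc - P) @ (jc - L)) < 1e-9 * d * d

    def test_offset_at_segment_length_errors(self):
        with pytest.raises(GeometryError, match="exceeds segment length"):
            ck.chord_joint_center((0, 0, 10), (0, 0, 0), (5, 0, 5), 10.0)

    def test_collinear_inputs_error(self):
        with pytest.raises(GeometryError, match="collinear"):
            ck.chord_joint_center((0, 0, 10), (0, 0, 0), (0, 0, 5), 4.0)


class TestPelvisFrame:
    def test_aligned_configuration(self):
        f = ck.pelvis_frame((0, 120, 1000), (0, -120, 1000), (-150, 0, 1000))
        assert np.allclose(f.origin, [0, 0, 1000])
        assert np.allclose(f.x, [1, 0, 0]) and np.allclose(f.y, [0, 1, 0])
        assert np.allclose(f.z, [0, 0, 1])

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(5)
        Q = random_rotation(rng)
        base = [np.array(p, dtype=float) for p in
                ((0, 120, 1000), (0, -120, 1000), (-150, 0, 1000))]
        f0 = ck.pelvis_frame(*base)
        f1 = ck.pelvis_frame(*(Q @ p for p in base))
        for a0, a1 in ((f0.x, f1.x), (f0.y, f1.y), (f0.z, f1.z)):
            assert np.allclose(Q @ a0, a1, atol=1e-12)

    def test_coincident_asis_error(self):
        with pytest.raises(GeometryError):
            ck.pelvis_frame((0, 0, 0), (0, 0, 0), (-150, 0, 0))


class TestHipRegression:
    def test_davis_arithmetic(self):
        p = ck.HipRegressionParams()
        assert p.c_slope * 940 + p.c_intercept == pytest.approx(92.8)
        assert p.at_default(940) == pytest.approx(72.512)

    def test_hip_centers_below_asis_plane_and_lateral(self, subject, calib):
        pelvis = ck.pelvis_frame((0, 120, 1000), (0, -120, 1000), (-150, 0, 1000))
        left, right = ck.hip_joint_centers(pelvis, calib.measurements, calib)
        assert (left - pelvis.origin) @ pelvis.z < 0
        assert (right - pelvis.origin) @ pelvis.z < 0
        assert (left - pelvis.origin) @ pelvis.y > 0   # toward subject's left
        assert (right - pelvis.origin) @ pelvis.y < 0

    def test_harrington_degenerate_table(self, subject):
        from dataclasses import replace
        h = ck.HarringtonCoefficients(a1=0, b1=-10, a2=0, c2=0, b2=0,
                                      a3=0, c3=0, b3=0)
        params = replace(ck.HipRegressionParams(), harrington=h)
        L, R = ck.hip_centers_harrington(
            (0, 120, 1000), (0, -120, 1000), (-150, 50, 1000),
            (-150, -50, 1000), subject.measurements, params)
        assert np.allclose(L, [-10, 0, 1000]) and np.allclose(R, [-10, 0, 1000])

    def test_harrington_mirror_symmetry(self, subject):
        rng = np.random.default_rng(11)
        LASI = np.array([10.0, 120.0, 990.0]) + rng.normal(scale=5, size=3)
        RASI = LASI * [1, -1, 1]
        LPSI = np.array([-150.0, 50.0, 1010.0])
        RPSI = LPSI * [1, -1, 1]
        L, R = ck.hip_centers_harrington(LASI, RASI, LPSI, RPSI,
                                         subject.measurements)
        assert np.allclose(L * [1, -1, 1], R, atol=1e-9)

    def test_missing_coefficients_never_fall_back(self, subject):
        from dataclasses import replace
        params = replace(ck.HipRegressionParams(), harrington=None)
        with pytest.raises(ConfigurationError):
            ck.hip_centers_harrington((0, 120, 1000), (0, -120, 1000),
                                      (-150, 50, 1000), (-150, -50, 1000),
                                      subject.measurements, params)


class TestKneeMedial:
    def test_midpoint_and_axis(self):
        jc, axis = ck.knee_center_medial((0, 0, 0), (0, 100, 0))
        assert np.allclose(jc, [0, 50, 0]) and np.allclose(axis, [0, 1, 0])

    def test_equidistance_property(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.normal(scale=100, size=(2, 3))
            jc, _ = ck.knee_center_medial(a, b)
            assert np.isclose(np.linalg.norm(jc - a), np.linalg.norm(jc - b))

    def test_coincident_markers_error(self):
        with pytest.raises(GeometryError):
            ck.knee_center_medial((1, 2, 3), (1, 2, 3))


class TestCardan:
    def test_identity(self):
        f = SegmentFrame.identity()
        assert cardan_angles(f, f) == (0.0, 0.0, 0.0)

    def test_pure_120_degree_flexion(self):
        prox = SegmentFrame.identity()
        dist = SegmentFrame.from_rotation(compose_cardan(120.0, 0.0, 0.0))
        a, b, g = cardan_angles(prox, dist)
        assert a == pytest.approx(120.0, abs=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert g == pytest.approx(0.0, abs=1e-9)

    def test_compose_matches_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b, g = rng.uniform([-179, -89, -179], [179, 89, 179])
            ours = compose_cardan(a, b, g)
            ref = Rotation.from_euler("YXZ", [a, b, g], degrees=True).as_matrix()
            assert np.allclose(ours, ref, atol=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(a=st.floats(-179.9, 179.9), b=st.floats(-89.0, 89.0),
           g=st.floats(-179.9, 179.9))
    def test_compose_decompose_round_trip(self, a, b, g):
        dist = SegmentFrame.from_rotation(compose_cardan(a, b, g))
        ra, rb, rg = cardan_angles(SegmentFrame.identity(), dist)
        assert ra == pytest.approx(a, abs=1e-9)
        assert rb == pytest.approx(b, abs=1e-9)
        assert rg == pytest.approx(g, abs=1e-9)

    def test_arcsin_decomposition_fails_beyond_90(self):
        """Negative control: the arcsine formulation folds 120 degrees of
        flexion back to 60; the arctangent path does not."""
        M = compose_cardan(120.0, 0.0, 0.0)
        arcsin_alpha = math.degrees(math.asin(M[0, 2]))
        assert arcsin_alpha == pytest.approx(60.0, abs=1e-9)
        dist = SegmentFrame.from_rotation(M)
        assert cardan_angles(SegmentFrame.identity(), dist)[0] == pytest.approx(
            120.0, abs=1e-9)


class TestSegmentFramesAndOrchestrator:
    def test_neutral_pose_femur_axis_vertical(self, subject, static_trial, calib):
        rec = ck.frame_kinematics(static_trial.frame_markers(0), calib)
        assert rec.valid_left and rec.valid_right
        assert np.nanmax(np.abs(rec.angles)) < 1e-6

    def test_kjc_at_chord_offset_from_knee_marker(self, subject, calib, squat_run):
        from cgmkin.cgm_core import segment_frames, pelvis_frame, hip_joint_centers
        markers = squat_run["dynamic"].frame_markers(20)
        pelvis = pelvis_frame(markers["LASI"], markers["RASI"],
                              0.5 * (markers["LPSI"] + markers["RPSI"]))
        hjc_l, _ = hip_joint_centers(pelvis, calib.measurements, calib)
        side = {k[1:]: markers["L" + k[1:]] for k in
                ("LTHI", "LKNE", "LTIB", "LANK", "LTOE")}
        frames = segment_frames(side, hjc_l, calib.measurements, calib, "L")
        expected = calib.measurements.left_knee_width / 2 + calib.measurements.marker_radius
        assert abs(np.linalg.norm(frames.kjc - markers["LKNE"]) - expected) < 1e-9

    def test_aw_change_leaves_kjc_and_femur_untouched(self, subject, static_trial,
                                                      squat_run):
        m2 = subject.measurements.with_offsets(aw=7.0)
        c1 = ck.run_static(static_trial, subject.measurements)
        c2 = ck.run_static(static_trial, m2)
        opts = ck.KinematicsOptions(store_axes=True)
        r1 = ck.frame_kinematics(squat_run["dynamic"].frame_markers(10), c1,
                                 options=opts)
        r2 = ck.frame_kinematics(squat_run["dynamic"].frame_markers(10), c2,
                                 options=opts)
        from cgmkin.series import SEGMENTS
        for seg in ("Pelvis", "LFemur", "RFemur"):
            i = SEGMENTS.index(seg)
            assert np.array_equal(r1.axes[i], r2.axes[i])
        assert not np.array_equal(r1.axes[SEGMENTS.index("LTibia")],
                                  r2.axes[SEGMENTS.index("LTibia")])

    def test_missing_left_knee_invalidates_left_side_only(self, calib, squat_run):
        markers = dict(squat_run["dynamic"].frame_markers(5))
        markers["LKNE"] = None
        rec = ck.frame_kinematics(markers, calib)
        assert not rec.valid_left and rec.valid_right
        assert np.isnan(rec.angles[3])          # LHip_X flagged, not zeroed
        assert np.isfinite(rec.angles[6])       # RHip_X computed

    def test_medial_marker_used_per_frame(self, squat_run):
        subj = ck.default_subject(include_medial_knee=True)
        static = ck.make_static_trial(subj, 3)
        opts = ck.KinematicsOptions(knee_method="medial")
        c = ck.run_static(static, subj.measurements, opts)
        dyn, truth = ck.make_dynamic_trial(subj, ck.MotionProgram.squat(7, 60))
        markers = dict(dyn.frame_markers(3))
        with_knm = ck.frame_kinematics(markers, c, options=opts)
        markers["LKNM"] = None  # falls back to the chord for this frame
        without = ck.frame_kinematics(markers, c, options=opts)
        assert with_knm.valid_left and without.valid_left
        # generator places KNM so both paths agree here
        assert np.allclose(with_knm.angles[3:6], without.angles[3:6], atol=1e-9)
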