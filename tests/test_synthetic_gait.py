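"""The forward-kinematic generator: template consistency, round trips
through the engine, determinism and noise behavior."""

import numpy as np
import pytest

import cgmkin as ck
from cgmkin.errors import ValidationError


class TestStaticTrial:
    def test_neutral_static_gives_zero_ankle_offsets(self, calib):
        assert np.allclose(calib.ankle_offset_left, 0, atol=1e-6)
        assert np.allclose(calib.ankle_offset_right, 0, atol=1e-6)

    def test_inter_asis_equals_template_width(self, calib, subject):
        assert calib.inter_asis_measured == subject.asis_separation

    def test_chord_recovers_template_knee_center(self, subject, static_trial):
        """Construction/inversion oracle: the engine's chord applied to the
        generated HJC/KNE/THI lands on the generator's knee center."""
        c = subject.calibration_snapshot()
        markers = static_trial.frame_markers(0)
        pelvis = ck.pelvis_frame(markers["LASI"], markers["RASI"],
                                 0.5 * (markers["LPSI"] + markers["RPSI"]))
        hjc_l, _ = ck.hip_joint_centers(pelvis, c.measurements, c,
                                        subject.params)
        kjc = ck.chord_joint_center(
            hjc_l, markers["LKNE"], markers["LTHI"],
            subject.measurements.left_knee_width / 2)
        expected = hjc_l - subject.femur_length * np.array([0.0, 0.0, 1.0])
        assert np.linalg.norm(kjc - expected) < 1e-9

    def test_template_inconsistency_rejected(self, subject):
        with pytest.raises(ck.GenerationError, match="template inconsistency"):
            ck.SyntheticSubject(measurements=subject.measurements,
                                femur_length=100.0)


class TestDynamicTrial:
    def test_all_zero_program_equals_static_framewise(self, subject):
        static = ck.make_static_trial(subject, 4)
        dyn, truth = ck.make_dynamic_trial(subject,
                                           ck.MotionProgram.neutral(4))
        assert np.array_equal(static.positions, dyn.positions)
        assert np.allclose(truth.angles, 0, atol=1e-12)

    def test_squat_recovers_prescribed_peak_flexion(self, squat_run):
        truth, series = squat_run["truth"], squat_run["series"]
        peak = int(np.argmax(truth.channel("LKnee_X")))
        assert truth.channel("LKnee_X")[peak] == pytest.approx(120.0)
        assert series.channel("LKnee_X")[peak] == pytest.approx(120.0, abs=1e-6)
        assert series.channel("RKnee_X")[peak] == pytest.approx(120.0, abs=1e-6)

    def test_full_series_round_trip(self, squat_run):
        err = np.abs(squat_run["series"].angles - squat_run["truth"].angles)
        assert np.nanmax(err) < 1e-6

    def test_mirror_symmetry_of_symmetric_program(self, squat_run):
        from cgmkin.series import LEFT_CHANNELS, RIGHT_CHANNELS
        s = squat_run["series"].angles
        assert np.nanmax(np.abs(s[:, LEFT_CHANNELS] - s[:, RIGHT_CHANNELS])) < 1e-6

    def test_deterministic(self, subject):
        p = ck.MotionProgram.squat(9, 80)
        a, _ = ck.make_dynamic_trial(subject, p)
        b, _ = ck.make_dynamic_trial(subject, p)
        assert np.array_equal(a.positions, b.positions)

    def test_measurement_perturbation_follows_dependency_structure(
            self, subject, static_trial, squat_run):
        """Perturbing the measurement (not the markers) of a generated
        trial moves exactly the joints the hierarchy predicts."""
        base = squat_run["series"]
        m2 = subject.measurements.with_offsets(kw=6.0)
        c2 = ck.run_static(static_trial, m2)
        s2 = ck.process_trial(squat_run["dynamic"], c2)
        diff = np.abs(s2.angles - base.angles)
        assert not diff[:, 0:3].any()            # pelvis untouched
        assert diff[:, 3:21].max() > 1e-3        # hip chain moves

    def test_program_validation(self):
        with pytest.raises(ValidationError):
            ck.MotionProgram(n_frames=0)
        with pytest.raises(ValidationError):
            ck.MotionProgram(n_frames=5, windows={"bad": (0, 9)})


class TestNoise:
    def test_zero_sd_identical(self, squat_run):
        out = ck.add_noise(squat_run["dynamic"], 0.0, seed=3)
        assert np.array_equal(out.positions, squat_run["dynamic"].positions)

    def test_negative_sd_rejected(self, squat_run):
        with pytest.raises(ValidationError):
            ck.add_noise(squat_run["dynamic"], -1.0)

    def test_same_seed_same_noise(self, squat_run):
        a = ck.add_noise(squat_run["dynamic"], 1.0, seed=11)
        b = ck.add_noise(squat_run["dynamic"], 1.0, seed=11)
        assert np.array_equal(a.positions, b.positions)

    def test_sample_sd_matches_target(self, subject):
        dyn, _ = ck.make_dynamic_trial(subject, ck.MotionProgram.neutral(60))
        noisy = ck.add_noise(dyn, 1.0, seed=5)
        disp = noisy.positions - dyn.positions
        assert abs(disp.std() - 1.0) < 0.05

    def test_recovery_degrades_gracefully(self, subject, static_trial, calib,
                                          squat_run):
        """2 mm of marker noise perturbs but does not flip the recovered
        squat: the peak knee flexion stays near 120 degrees."""
        noisy = ck.add_noise(squat_run["dynamic"], 2.0, seed=8)
        series = ck.process_trial(noisy, calib)
        peak = np.nanmax(series.channel("LKnee_X"))
        assert 100.0 < peak < 140.0
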