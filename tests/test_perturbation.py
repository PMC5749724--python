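"""Offset grids, percent presets, batch recomputation and error summaries."""

import numpy as np
import pandas as pd
import pytest

import cgmkin as ck
from cgmkin.errors import ValidationError
from cgmkin.perturbation import (MEASUREMENTS, PerturbationResult,
                                 PerturbationSpec, apply_offsets,
                                 summarize_errors)
from cgmkin.series import JointAngleSeries


class TestGrids:
    def test_fine_grid_cardinality(self):
        grid = ck.build_offset_grid(ck.fine_spec())
        assert grid.shape == (21 ** 3, 5)

    def test_coarse_grid_cardinality(self):
        grid = ck.build_offset_grid(ck.coarse_spec())
        assert grid.shape == (9 ** 3, 5)

    def test_single_zero_vector(self):
        grid = ck.build_offset_grid(PerturbationSpec(
            {"LL": (0.0,), "KW": (0.0,), "AW": (0.0,)}))
        assert grid.shape == (1, 5) and not grid.any()

    def test_duplicate_grids_deduplicated(self):
        grid = ck.build_offset_grid([ck.fine_spec(), ck.fine_spec()])
        assert grid.shape == (21 ** 3, 5)

    def test_union_of_fine_and_coarse_drops_shared_vectors(self):
        fine = ck.build_offset_grid(ck.fine_spec())
        coarse = ck.build_offset_grid(ck.coarse_spec())
        union = ck.build_offset_grid([ck.fine_spec(), ck.coarse_spec()])
        shared = {tuple(v) for v in fine} & {tuple(v) for v in coarse}
        assert union.shape[0] == fine.shape[0] + coarse.shape[0] - len(shared)

    def test_deterministic_lexicographic_order(self):
        a = ck.build_offset_grid(ck.coarse_spec())
        b = ck.build_offset_grid(ck.coarse_spec())
        assert np.array_equal(a, b)
        assert np.array_equal(a, a[np.lexsort(a.T[::-1])])

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            PerturbationSpec({"LL": ()}).validate()


class TestPercentPresets:
    def test_leg_length_five_percent_is_47mm(self, subject):
        vecs = ck.percent_offsets(subject.measurements, {"LL": 5.0})
        assert sorted(v[0] for v in vecs) == [-47.0, 47.0]

    def test_knee_width_presets(self, subject):
        five = ck.percent_offsets(subject.measurements, {"KW": 5.0})
        ten = ck.percent_offsets(subject.measurements, {"KW": 10.0})
        assert sorted(v[1] for v in five) == [-5.25, 5.25]
        assert sorted(v[1] for v in ten) == [-10.5, 10.5]

    def test_all_sign_combinations(self, subject):
        vecs = ck.percent_offsets(subject.measurements,
                                  {"LL": 5.0, "KW": 5.0, "AW": 10.0})
        assert vecs.shape == (8, 5)
        assert len({tuple(v) for v in vecs}) == 8

    def test_nonpositive_percent_rejected(self, subject):
        with pytest.raises(ValidationError):
            ck.percent_offsets(subject.measurements, {"LL": 0.0})


@pytest.fixture(scope="module")
def short_inputs(subject):
    static = ck.make_static_trial(subject, 3)
    dynamic, _ = ck.make_dynamic_trial(subject, ck.MotionProgram.squat(12, 90))
    return static, dynamic


class TestRunPerturbations:
    def test_zero_offset_error_series_identically_zero(self, subject,
                                                       short_inputs):
        static, dynamic = short_inputs
        results = ck.run_perturbations(static, dynamic, subject.measurements,
                                       np.zeros((1, 5)))
        assert not results[0].failed
        assert not results[0].errors.any()

    def test_aw_only_offsets_leave_pelvis_and_hip_untouched(self, subject,
                                                            short_inputs):
        static, dynamic = short_inputs
        offsets = np.zeros((3, 5))
        offsets[:, 2] = (-10.0, 5.0, 15.0)
        results = ck.run_perturbations(static, dynamic, subject.measurements,
                                       offsets)
        for r in results:
            assert not r.failed
            assert not r.errors[:, 0:9].any()         # pelvis + both hips
            assert np.abs(r.errors[:, 15:21]).max() > 0  # ankles move

    def test_breaking_variant_flagged_others_continue(self, subject,
                                                      short_inputs):
        static, dynamic = short_inputs
        offsets = np.zeros((2, 5))
        offsets[1, 1] = 2000.0  # knee width beyond the thigh length
        results = ck.run_perturbations(static, dynamic, subject.measurements,
                                       offsets)
        assert not results[0].failed
        assert results[1].failed and "exceeds segment length" in results[1].reason

    def test_worker_count_never_changes_values(self, subject, short_inputs):
        static, dynamic = short_inputs
        offsets = np.zeros((4, 5))
        offsets[:, 0] = (-5, 0, 5, 10)
        serial = ck.run_perturbations(static, dynamic, subject.measurements,
                                      offsets, n_workers=1)
        parallel = ck.run_perturbations(static, dynamic, subject.measurements,
                                        offsets, n_workers=3)
        for a, b in zip(serial, parallel):
            assert np.array_equal(a.errors, b.errors, equal_nan=True)

    def test_at_offset_applies_to_resolved_default(self, subject, calib):
        m = apply_offsets(subject.measurements, (0, 0, 0, 10.0, 0), calib)
        assert m.left_asis_trochanter == pytest.approx(
            calib.resolved_at_left + 10.0)


def _toy_result(errors, offsets=(0, 0, 0, 0, 0)):
    n = errors.shape[0]
    series = JointAngleSeries(np.zeros((n, 23)))
    return PerturbationResult(np.asarray(offsets, float), series, errors)


class TestSummaries:
    def test_two_frame_toy_brute_force(self):
        """hipX errors (0.1, 0.3), kneeY (0.2, 0.25): window max hipX is
        0.3, the argmax joint is the hip and the argmax frame is 1."""
        err = np.zeros((2, 23))
        err[:, 3] = (0.1, 0.3)     # LHip_X
        err[:, 13] = (0.2, 0.25)   # RKnee_Y
        s = summarize_errors([_toy_result(err)])
        wm = s.window_max.set_index(["joint", "axis"])["max_error_deg"]
        assert wm[("Hip", "X")] == pytest.approx(0.3)
        assert wm[("Knee", "Y")] == pytest.approx(0.25)
        assert s.joint_counts.loc["Hip", "joint_count"] == 1
        assert s.joint_counts.loc["Hip", "max_frame"] == 1

    def test_zero_errors_tie_rule(self):
        s = summarize_errors([_toy_result(np.zeros((3, 23)))])
        assert (s.window_max["max_error_deg"] == 0).all()
        assert s.joint_counts.loc["Hip", "joint_count"] == 1  # hip first
        assert s.joint_counts.loc["Total", "max_frame"] == 0  # lowest frame

    def test_joint_counts_partition_variants(self):
        rng = np.random.default_rng(0)
        results = [_toy_result(np.abs(rng.normal(size=(5, 23))))
                   for _ in range(17)]
        s = summarize_errors(results)
        joints = s.joint_counts.drop(index="Total")
        assert joints["joint_count"].sum() == 17 == s.n_successful

    def test_axis_counts_sum_per_joint_side(self):
        rng = np.random.default_rng(1)
        results = [_toy_result(np.abs(rng.normal(size=(4, 23))))
                   for _ in range(9)]
        s = summarize_errors(results)
        assert (s.axis_counts.groupby(level="side").sum() == 9).all().all()

    def test_window_max_monotone_in_window(self):
        rng = np.random.default_rng(2)
        res = [_toy_result(np.abs(rng.normal(size=(10, 23))))]
        full = summarize_errors(res, {"full": (0, 10)})
        sub = summarize_errors(res, {"sub": (3, 6)})
        assert (full.window_max["max_error_deg"].to_numpy()
                >= sub.window_max["max_error_deg"].to_numpy() - 1e-15).all()

    def test_empty_results_error(self):
        with pytest.raises(ValidationError):
            summarize_errors([])
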