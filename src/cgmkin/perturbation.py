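"""Systematic subject-measurement error analysis.

Generates offset grids over the anthropometric measurements (permutations
with repetitions: n possible values to the power of r measurements),
re-runs the full pipeline for each offset vector — static recalibration
included, since the ankle offsets depend on the widths — and summarizes
the per-channel angle errors against the unperturbed baseline.

Measurement order in every offset vector: LL, KW, AW, AT, IAD
(leg length, knee width, ankle width, ASIS-trochanter, inter-ASIS), all
in millimetres, applied identically to the left and right side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import partial

import numpy as np
import pandas as pd

from .cgm_core import KinematicsOptions, process_trial
from .errors import CalibrationError, GeometryError, ValidationError
from .io_formats import MarkerTrial, SubjectMeasurements
from .parallel_exec import map_indexed
from .series import JointAngleSeries
from .static_calibration import StaticCalibration, run_static

__all__ = [
    "MEASUREMENTS", "PerturbationSpec", "PerturbationResult",
    "fine_spec", "coarse_spec", "build_offset_grid", "percent_offsets",
    "apply_offsets", "run_perturbations", "summarize_errors",
    "PerturbationSummary",
]

MEASUREMENTS = ("LL", "KW", "AW", "AT", "IAD")

_JOINTS = ("Hip", "Knee", "Ankle")
_AXES = ("X", "Y", "Z")
# channel index of (joint, side): left/right X-channel starts
_JOINT_BASE = {("Hip", "L"): 3, ("Hip", "R"): 6,
               ("Knee", "L"): 9, ("Knee", "R"): 12,
               ("Ankle", "L"): 15, ("Ankle", "R"): 18}


@dataclass(frozen=True)
class PerturbationSpec:
    """Per-measurement offset value lists (mm)."""

    offsets: dict = field(default_factory=dict)

    def validate(self) -> "PerturbationSpec":
        for key, values in self.offsets.items():
            if key not in MEASUREMENTS:
                raise ValidationError(
                    f"unknown measurement {key!r}; expected one of {MEASUREMENTS}")
            if len(tuple(values)) == 0:
                raise ValidationError(f"offset list for {key} is empty")
            if not np.isfinite(np.asarray(values, dtype=float)).all():
                raise ValidationError(f"offset list for {key} has non-finite values")
        return self


def fine_spec() -> PerturbationSpec:
    """Intervals of 0.5 mm from -5 to +5 for LL, KW and AW: 21^3 = 9261
    combinations."""
    values = tuple(i * 0.5 for i in range(-10, 11))
    return PerturbationSpec({k: values for k in ("LL", "KW", "AW")})


def coarse_spec(values=(  -80.0, -40.0, -20.0, -10.0, 0.0,
                          10.0, 20.0, 40.0, 80.0)) -> PerturbationSpec:
    """A wide doubling-increment range, 0 to +/-80 mm, for LL, KW and AW:
    9^3 = 729 combinations with the default value set."""
    return PerturbationSpec({k: tuple(values) for k in ("LL", "KW", "AW")})


def build_offset_grid(spec) -> np.ndarray:
    """Cartesian product of the per-measurement offset lists.

    ``spec`` may be a single PerturbationSpec or an iterable of them
    (grids are concatenated).  Exact-duplicate vectors are removed and
    the result is ordered lexicographically over (LL, KW, AW, AT, IAD),
    so the grid is deterministic.
    """
    specs = [spec] if isinstance(spec, PerturbationSpec) else list(spec)
    if not specs:
        raise ValidationError("no perturbation specs given")
    rows = []
    for s in specs:
        s.validate()
        lists = [tuple(float(v) for v in s.offsets.get(k, (0.0,)))
                 for k in MEASUREMENTS]
        rows.extend(itertools.product(*lists))
    if not rows:
        raise ValidationError("offset grid is empty")
    grid = np.unique(np.asarray(rows, dtype=np.float64), axis=0)
    return grid


def percent_offsets(meas: SubjectMeasurements, percents: dict) -> np.ndarray:
    """Offset vectors for percent presets: +/- p% of the baseline per
    measurement, all sign combinations (so k measurements give 2^k
    vectors)."""
    baselines = {
        "LL": meas.mean_leg_length,
        "KW": 0.5 * (meas.left_knee_width + meas.right_knee_width),
        "AW": 0.5 * (meas.left_ankle_width + meas.right_ankle_width),
        "AT": (None if meas.left_asis_trochanter is None
               or meas.right_asis_trochanter is None
               else 0.5 * (meas.left_asis_trochanter + meas.right_asis_trochanter)),
        "IAD": meas.inter_asis_distance,
    }
    keys = []
    deltas = []
    for key, p in percents.items():
        if key not in MEASUREMENTS:
            raise ValidationError(f"unknown measurement {key!r}")
        if not p > 0:
            raise ValidationError(f"percent for {key} must be positive, got {p}")
        base = baselines[key]
        if base is None:
            raise ValidationError(f"percent offset for {key} needs a baseline value")
        keys.append(key)
        deltas.append(p / 100.0 * base)
    if not keys:
        raise ValidationError("no percent presets given")
    vectors = []
    for signs in itertools.product((-1.0, 1.0), repeat=len(keys)):
        vec = dict.fromkeys(MEASUREMENTS, 0.0)
        for key, d, sgn in zip(keys, deltas, signs):
            vec[key] = sgn * d
        vectors.append([vec[k] for k in MEASUREMENTS])
    return np.asarray(vectors, dtype=np.float64)


def apply_offsets(meas: SubjectMeasurements, vector,
                  baseline: StaticCalibration | None = None) -> SubjectMeasurements:
    """Apply one (LL, KW, AW, AT, IAD) offset vector to both sides.

    AT and IAD offsets are applied on top of the baseline calibration's
    resolved values when the raw measurements leave them unset.
    """
    ll, kw, aw, at, iad = (float(v) for v in np.asarray(vector, dtype=float))
    m = meas
    if at and (m.left_asis_trochanter is None or m.right_asis_trochanter is None):
        if baseline is None:
            raise ValidationError(
                "AT offset on an unset measurement needs a baseline calibration")
        m = replace(m, left_asis_trochanter=baseline.resolved_at_left,
                    right_asis_trochanter=baseline.resolved_at_right)
    if iad and m.inter_asis_distance is None:
        if baseline is None:
            raise ValidationError(
                "IAD offset on an unset measurement needs a baseline calibration")
        m = replace(m, inter_asis_distance=baseline.inter_asis_effective)
    return m.with_offsets(ll=ll, kw=kw, aw=aw, at=at, iad=iad)


@dataclass
class PerturbationResult:
    """One offset vector's recomputed angles and error vs baseline."""

    offsets: np.ndarray
    series: JointAngleSeries | None
    errors: np.ndarray | None        # (n_frames, 23), variant - baseline
    failed: bool = False
    reason: str | None = None

    @property
    def max_abs_error(self) -> np.ndarray | None:
        if self.errors is None:
            return None
        return np.nan_to_num(np.abs(self.errors), nan=0.0).max(axis=0)


def _run_variant(i: int, static=None, dynamic=None, meas=None, offsets=None,
                 options=None, baseline_calib=None, baseline_angles=None):
    vec = offsets[i]
    try:
        meas_v = apply_offsets(meas, vec, baseline_calib)
        calib_v = run_static(static, meas_v, options)
        series = process_trial(dynamic, calib_v, options)
    except (CalibrationError, GeometryError, ValidationError) as e:
        return PerturbationResult(vec, None, None, failed=True, reason=str(e))
    geo = [d for d in series.diagnostics if "geometry:" in d]
    if geo:
        return PerturbationResult(vec, series, None, failed=True, reason=geo[0])
    errors = series.angles - baseline_angles
    return PerturbationResult(vec, series, errors)


def run_perturbations(static: MarkerTrial, dynamic: MarkerTrial,
                      meas: SubjectMeasurements, offsets,
                      options: KinematicsOptions | None = None,
                      n_workers: int = 1) -> list[PerturbationResult]:
    """Recompute the dynamic trial for every offset vector.

    Each variant re-runs the static calibration with the offset
    measurements (the ankle offsets depend on the widths) before the
    dynamic pass.  Variants that break a chord precondition are flagged
    failed with the reason; the run continues.  The worker count only
    distributes variants — it never changes values.
    """
    options = options or KinematicsOptions()
    offsets = np.atleast_2d(np.asarray(offsets, dtype=np.float64))
    if offsets.shape[1] != len(MEASUREMENTS):
        raise ValidationError(
            f"offset vectors must have {len(MEASUREMENTS)} components "
            f"(order {MEASUREMENTS})")
    baseline_calib = run_static(static, meas, options)
    baseline = process_trial(dynamic, baseline_calib, options)
    fn = partial(_run_variant, static=static, dynamic=dynamic, meas=meas,
                 offsets=offsets, options=options,
                 baseline_calib=baseline_calib,
                 baseline_angles=baseline.angles)
    return map_indexed(fn, offsets.shape[0], n_workers)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class PerturbationSummary:
    """Error summaries across variants.

    window_max: per window x joint x axis, the maximum absolute error
    combining sides, offset signs and variants.
    joint_counts: how often each joint contains a variant's largest
    error, how many distinct frames carry those maxima, and the modal
    frame with its count.
    axis_counts: per side and axis, how often that axis holds the
    largest error within each joint across variants.
    Ties break by the fixed order hip < knee < ankle, then X < Y < Z,
    then the lowest frame index.  Frames are 0-based.
    """

    window_max: pd.DataFrame
    joint_counts: pd.DataFrame
    axis_counts: pd.DataFrame
    n_successful: int
    n_failed: int

    def write(self, out_dir) -> None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        self.window_max.to_csv(os.path.join(out_dir, "window_max.csv"), index=False)
        self.joint_counts.to_csv(os.path.join(out_dir, "joint_counts.csv"))
        self.axis_counts.to_csv(os.path.join(out_dir, "axis_counts.csv"))


def _error_tensor(result: PerturbationResult) -> np.ndarray:
    """(joint, axis, side, frame) absolute errors, NaN -> 0."""
    err = np.nan_to_num(np.abs(result.errors), nan=0.0)
    n = err.shape[0]
    out = np.zeros((3, 3, 2, n))
    for j, joint in enumerate(_JOINTS):
        for si, side in enumerate("LR"):
            base = _JOINT_BASE[(joint, side)]
            out[j, :, si, :] = err[:, base:base + 3].T
    return out


def summarize_errors(results, frame_windows: dict | None = None) -> PerturbationSummary:
    ok = [r for r in results if not r.failed and r.errors is not None]
    n_failed = len(results) - len(ok)
    if not ok:
        raise ValidationError("no successful perturbation results to summarize")
    n = ok[0].errors.shape[0]
    windows = frame_windows or {"all": (0, n)}
    for name, (a, b) in windows.items():
        if not (0 <= a < b <= n):
            raise ValidationError(
                f"frame window {name!r} = ({a}, {b}) outside [0, {n})")

    tensors = [_error_tensor(r) for r in ok]
    combined = np.maximum.reduce(tensors)          # over variants
    combined_sides = combined.max(axis=2)          # over sides -> (j, a, f)

    rows = []
    for wname, (a, b) in windows.items():
        for j, joint in enumerate(_JOINTS):
            for ai, axis in enumerate(_AXES):
                rows.append({"window": wname, "joint": joint, "axis": axis,
                             "max_error_deg": combined_sides[j, ai, a:b].max()})
    window_max = pd.DataFrame(rows)

    # per-variant argmax joint and frame (sides combined before argmax)
    joint_of = []
    frame_of = []
    for t in tensors:
        flat = t.max(axis=2)                       # (j, a, f)
        idx = np.unravel_index(np.argmax(flat), flat.shape)
        joint_of.append(idx[0])
        frame_of.append(idx[2])
    joint_of = np.asarray(joint_of)
    frame_of = np.asarray(frame_of)

    def _modal(frames: np.ndarray):
        if frames.size == 0:
            return 0, 0
        counts = np.bincount(frames, minlength=n)
        best = int(np.argmax(counts))
        return best, int(counts[best])

    jc_rows = {}
    total_modal, total_modal_count = _modal(frame_of)
    jc_rows["Total"] = {"joint_count": len(ok),
                        "n_frames": int(np.unique(frame_of).size),
                        "max_frame": total_modal,
                        "max_frame_count": total_modal_count}
    for j, joint in enumerate(_JOINTS):
        sel = frame_of[joint_of == j]
        modal, modal_count = _modal(sel)
        jc_rows[joint] = {"joint_count": int((joint_of == j).sum()),
                          "n_frames": int(np.unique(sel).size),
                          "max_frame": modal if sel.size else 0,
                          "max_frame_count": modal_count if sel.size else 0}
    joint_counts = pd.DataFrame.from_dict(jc_rows, orient="index")

    ax_counts = np.zeros((2, 3, 3), dtype=int)     # (side, axis, joint)
    for t in tensors:
        for si in range(2):
            for j in range(3):
                per_axis = t[j, :, si, :].max(axis=1)
                ax_counts[si, int(np.argmax(per_axis)), j] += 1
    idx = pd.MultiIndex.from_product([["Right", "Left"], list(_AXES)],
                                     names=["side", "axis"])
    data = np.vstack([ax_counts[1], ax_counts[0]])  # Right block first
    axis_counts = pd.DataFrame(data, index=idx, columns=list(_JOINTS))

    return PerturbationSummary(window_max, joint_counts, axis_counts,
                               n_successful=len(ok), n_failed=n_failed)
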