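"""Forward-kinematic generator of marker trials with known ground truth.

Builds a lower-body Plug-in-Gait-style marker set (ASIS/PSIS, thigh and
shank wands, lateral knee/ankle, heel, toe per side) by composing segment
frames from prescribed joint-angle waveforms and emitting markers from a
placement template.  The template is constructed around joint centers
computed with the same hip regression and chord conventions as the
kinematics engine, so a noiseless generated trial processed by the
engine reproduces the program's angles to numerical precision — any
divergence is a bug in one of the two.

The wand markers are placed laterally at mid-segment in the segment's
frontal plane: the chord construction recovers the joint center exactly
only when the wand lies in the plane spanned by the proximal center, the
lateral marker and the joint center itself.

One observability caveat: the engine reconstructs the foot frame from
the toe marker and the tibia long axis, so rotation of the foot about
its own long axis is not observable.  The returned ground-truth ankle
angles are therefore expressed in the same projected convention the
engine uses (for pure ankle flexion the two coincide).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cgm_core import (HipRegressionParams, SegmentFrame, compose_cardan,
                       hip_centers_harrington, hip_joint_centers)
from .errors import GenerationError, ValidationError
from .io_formats import MarkerTrial, SubjectMeasurements
from .series import N_CHANNELS, JointAngleSeries
from .static_calibration import StaticCalibration

__all__ = ["SyntheticSubject", "MotionProgram", "default_subject",
           "make_static_trial", "make_dynamic_trial", "add_noise"]

#: Fraction of leg length assigned to the thigh / shank segments.  Their
#: sum deliberately stays within 10% of LL (leg length is measured
#: ASIS-to-malleolus, not hip-center-to-ankle-center).
_FEMUR_FRACTION = 0.52
_TIBIA_FRACTION = 0.44
_LL_TOLERANCE = 0.10


def default_subject(**kwargs) -> "SyntheticSubject":
    """The default synthetic subject: leg length 940 mm, knee width
    105 mm, ankle width 70 mm — so percent presets map onto round
    millimetre offsets (5% of LL is 47 mm)."""
    meas = kwargs.pop("measurements", None) or SubjectMeasurements(
        left_leg_length=940.0, right_leg_length=940.0,
        left_knee_width=105.0, right_knee_width=105.0,
        left_ankle_width=70.0, right_ankle_width=70.0,
        subject_id="synthetic-default")
    return SyntheticSubject(measurements=meas, **kwargs)


@dataclass
class SyntheticSubject:
    """Anthropometry plus the marker-placement template.

    Template rules (segment coordinates): lateral knee/ankle markers sit
    at width/2 + marker_radius laterally of the joint center along the
    segment y axis; wands sit laterally at mid-segment in the frontal
    plane; toe and heel lie along the foot's long axis.
    """

    measurements: SubjectMeasurements
    pelvis_width: float = 240.0      # ASIS separation when IAD is unset
    psis_width: float = 100.0
    pelvis_depth: float = 150.0
    pelvis_height: float = 1000.0
    foot_length: float = 150.0
    heel_offset: float = 60.0
    thigh_wand_extra: float = 60.0
    shank_wand_extra: float = 50.0
    hip_method: str = "davis"
    include_medial_knee: bool = False
    params: HipRegressionParams = field(default_factory=HipRegressionParams)
    femur_length: float | None = None   # default: fraction of leg length
    tibia_length: float | None = None

    def __post_init__(self) -> None:
        self.measurements.validate()
        if self.hip_method not in ("davis", "harrington"):
            raise ValidationError(f"unknown hip_method {self.hip_method!r}")
        ll = self.measurements.mean_leg_length
        if self.femur_length is None:
            self.femur_length = _FEMUR_FRACTION * ll
        if self.tibia_length is None:
            self.tibia_length = _TIBIA_FRACTION * ll
        total = self.femur_length + self.tibia_length
        if abs(total - ll) > _LL_TOLERANCE * ll:
            raise GenerationError(
                f"template inconsistency: femur+tibia = {total:.1f} mm not "
                f"within {_LL_TOLERANCE:.0%} of leg length {ll:.1f} mm")

    @property
    def asis_separation(self) -> float:
        m = self.measurements
        return (m.inter_asis_distance if m.inter_asis_distance is not None
                else self.pelvis_width)

    def marker_labels(self) -> list[str]:
        labels = ["LASI", "RASI", "LPSI", "RPSI"]
        for s in "LR":
            labels += [f"{s}THI", f"{s}KNE", f"{s}TIB", f"{s}ANK",
                       f"{s}HEE", f"{s}TOE"]
            if self.include_medial_knee:
                labels.append(f"{s}KNM")
        return labels

    def calibration_snapshot(self) -> StaticCalibration:
        """The calibration the engine would derive from the static pose,
        used to place the hip centers consistently."""
        m = self.measurements
        sep = self.asis_separation
        eff = m.inter_asis_distance if m.inter_asis_distance is not None else sep
        at_default = self.params.at_default(m.mean_leg_length)
        at_l = (m.left_asis_trochanter if m.left_asis_trochanter is not None
                else at_default)
        at_r = (m.right_asis_trochanter if m.right_asis_trochanter is not None
                else at_default)
        from dataclasses import replace
        snap = replace(m, inter_asis_distance=eff,
                       left_asis_trochanter=at_l, right_asis_trochanter=at_r)
        return StaticCalibration(
            inter_asis_measured=sep, inter_asis_effective=eff,
            ankle_offset_left=(0.0, 0.0), ankle_offset_right=(0.0, 0.0),
            resolved_at_left=at_l, resolved_at_right=at_r,
            measurements=snap, n_frames_used=1)


@dataclass
class MotionProgram:
    """Per-joint angle waveforms (degrees vs frame) driving the forward
    model.  Channels are (flexion, abduction, rotation) per joint in the
    engine's output sign convention for both sides."""

    n_frames: int
    rate: float = 100.0
    pelvis: np.ndarray | None = None
    hip_l: np.ndarray | None = None
    hip_r: np.ndarray | None = None
    knee_l: np.ndarray | None = None
    knee_r: np.ndarray | None = None
    ankle_l: np.ndarray | None = None
    ankle_r: np.ndarray | None = None
    windows: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("a motion program needs at least one frame")
        for name in ("pelvis", "hip_l", "hip_r", "knee_l", "knee_r",
                     "ankle_l", "ankle_r"):
            v = getattr(self, name)
            if v is None:
                v = np.zeros((self.n_frames, 3))
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (self.n_frames, 3):
                raise ValidationError(
                    f"waveform {name} must be ({self.n_frames}, 3); got {v.shape}")
            if not np.isfinite(v).all():
                raise ValidationError(f"waveform {name} contains non-finite values")
            setattr(self, name, v)
        for name, (start, stop) in self.windows.items():
            if not (0 <= start < stop <= self.n_frames):
                raise ValidationError(
                    f"window {name!r} = ({start}, {stop}) outside [0, {self.n_frames})")

    @classmethod
    def neutral(cls, n_frames: int, rate: float = 100.0) -> "MotionProgram":
        return cls(n_frames=n_frames, rate=rate)

    @staticmethod
    def _bell(n_frames: int) -> np.ndarray:
        """A smooth 0 -> 1 -> 0 envelope that attains exactly 1 at the
        middle frame for any frame count."""
        if n_frames == 1:
            return np.ones(1)
        t = np.arange(n_frames, dtype=np.float64)
        p = (n_frames - 1) // 2
        up = np.sin(0.5 * math.pi * t / max(p, 1))
        down = np.sin(0.5 * math.pi * (n_frames - 1 - t) / (n_frames - 1 - p))
        return np.where(t <= p, up, down)

    @classmethod
    def squat(cls, n_frames: int = 500, peak_knee_flexion: float = 120.0,
              rate: float = 100.0) -> "MotionProgram":
        """A symmetric squat: knee flexion rises to ``peak_knee_flexion``
        at mid-trial (exercising the beyond-90-degree regime), with
        proportional hip flexion and ankle dorsiflexion."""
        bell = cls._bell(n_frames)
        knee = np.zeros((n_frames, 3))
        knee[:, 0] = peak_knee_flexion * bell
        hip = np.zeros((n_frames, 3))
        hip[:, 0] = -0.45 * peak_knee_flexion * bell
        ankle = np.zeros((n_frames, 3))
        ankle[:, 0] = 0.20 * peak_knee_flexion * bell
        return cls(n_frames=n_frames, rate=rate,
                   hip_l=hip, hip_r=hip.copy(),
                   knee_l=knee, knee_r=knee.copy(),
                   ankle_l=ankle, ankle_r=ankle.copy(),
                   windows={"squat": (0, n_frames)})

    @classmethod
    def leg_swing(cls, n_frames: int = 300, amplitude: float = 45.0,
                  rate: float = 100.0) -> "MotionProgram":
        """A single-leg frontal/sagittal swing with small abduction and
        rotation components — useful for exercising all channels."""
        bell = cls._bell(n_frames)
        hip_l = np.column_stack([amplitude * bell, 12.0 * bell, 8.0 * bell])
        knee_l = np.column_stack([0.5 * amplitude * bell, 5.0 * bell,
                                  -6.0 * bell])
        ankle_l = np.column_stack([10.0 * bell, 4.0 * bell, 0.0 * bell])
        return cls(n_frames=n_frames, rate=rate, hip_l=hip_l, knee_l=knee_l,
                   ankle_l=ankle_l, windows={"swing": (0, n_frames)})


def _decompose_yxz_deg(M: np.ndarray) -> tuple[float, float, float]:
    # local mirror of the engine's Y-X-Z arctan convention
    a = math.atan2(M[0, 2], M[2, 2])
    b = math.atan2(-M[1, 2], math.hypot(M[1, 0], M[1, 1]))
    g = math.atan2(M[1, 0], M[1, 1])
    return math.degrees(a), math.degrees(b), math.degrees(g)


def _emit_frame(subject: SyntheticSubject, calib: StaticCalibration,
                pelvis_ang, hips, knees, ankles, frame_no: int):
    """Markers and ground-truth channels for one frame."""
    m = subject.measurements
    mr = m.marker_radius
    sep, psep, pd = subject.asis_separation, subject.psis_width, subject.pelvis_depth
    o0 = np.array([0.0, 0.0, subject.pelvis_height])

    Rp = compose_cardan(*pelvis_ang)
    pelvis = SegmentFrame.from_rotation(Rp, o0)
    markers = {
        "LASI": o0 + Rp @ np.array([0.0, sep / 2, 0.0]),
        "RASI": o0 + Rp @ np.array([0.0, -sep / 2, 0.0]),
        "LPSI": o0 + Rp @ np.array([-pd, psep / 2, 0.0]),
        "RPSI": o0 + Rp @ np.array([-pd, -psep / 2, 0.0]),
    }
    if subject.hip_method == "harrington":
        hjc_l, hjc_r = hip_centers_harrington(
            markers["LASI"], markers["RASI"], markers["LPSI"],
            markers["RPSI"], calib.measurements, subject.params)
    else:
        hjc_l, hjc_r = hip_joint_centers(pelvis, calib.measurements, calib,
                                         subject.params)

    truth = np.full(N_CHANNELS, np.nan)
    truth[0:3] = pelvis_ang
    Lf, Lt = subject.femur_length, subject.tibia_length

    for side, hjc, hip_ang, knee_ang, ankle_ang in (
            ("L", hjc_l, hips[0], knees[0], ankles[0]),
            ("R", hjc_r, hips[1], knees[1], ankles[1])):
        lat = 1.0 if side == "L" else -1.0
        s = -1.0 if side == "L" else 1.0  # output-sign convention inverse
        if side == "L":
            dk = m.left_knee_width / 2 + mr
            da = m.left_ankle_width / 2 + mr
        else:
            dk = m.right_knee_width / 2 + mr
            da = m.right_ankle_width / 2 + mr

        Rf = Rp @ compose_cardan(hip_ang[0], s * hip_ang[1], s * hip_ang[2])
        kjc = hjc - Lf * Rf[:, 2]
        markers[f"{side}KNE"] = kjc + lat * dk * Rf[:, 1]
        markers[f"{side}THI"] = (hjc - 0.5 * Lf * Rf[:, 2]
                                 + lat * (dk + subject.thigh_wand_extra) * Rf[:, 1])
        if subject.include_medial_knee:
            markers[f"{side}KNM"] = kjc - lat * dk * Rf[:, 1]

        Rt = Rf @ compose_cardan(knee_ang[0], s * knee_ang[1], s * knee_ang[2])
        ajc = kjc - Lt * Rt[:, 2]
        markers[f"{side}ANK"] = ajc + lat * da * Rt[:, 1]
        markers[f"{side}TIB"] = (kjc - 0.5 * Lt * Rt[:, 2]
                                 + lat * (da + subject.shank_wand_extra) * Rt[:, 1])

        Rfo = Rt @ compose_cardan(ankle_ang[0], s * ankle_ang[1], s * ankle_ang[2])
        fx = Rfo[:, 0]
        markers[f"{side}TOE"] = ajc + subject.foot_length * fx
        markers[f"{side}HEE"] = ajc - subject.heel_offset * fx

        # engine-observable foot frame: toe direction + tibia long axis
        fy_raw = np.cross(Rt[:, 2], fx)
        if np.linalg.norm(fy_raw) < 1e-8:
            raise GenerationError(
                f"frame {frame_no}: {side} foot axis parallel to the tibia "
                "long axis (ankle flexion too close to +/-90 degrees)")
        fy = fy_raw / np.linalg.norm(fy_raw)
        fz = np.cross(fx, fy)
        Mt = Rt.T @ np.column_stack([fx, fy, fz])
        aa, ab, ag = _decompose_yxz_deg(Mt)
        ankle_truth = (aa, s * ab, s * ag)

        fh = fx - fx[2] * np.array([0.0, 0.0, 1.0])
        nfh = np.linalg.norm(fh)
        fp = math.nan if nfh < 1e-12 else math.degrees(
            math.atan2(fh[1] / nfh, fh[0] / nfh))

        base = {"L": 3, "R": 6}[side]
        truth[base:base + 3] = hip_ang
        truth[base + 6:base + 9] = knee_ang
        truth[base + 12:base + 15] = ankle_truth
        truth[21 if side == "L" else 22] = fp

    return markers, truth


def _render(subject: SyntheticSubject, program: MotionProgram):
    calib = subject.calibration_snapshot()
    labels = subject.marker_labels()
    n = program.n_frames
    positions = np.zeros((n, len(labels), 3))
    truths = np.zeros((n, N_CHANNELS))
    for i in range(n):
        markers, truth = _emit_frame(
            subject, calib, program.pelvis[i],
            (program.hip_l[i], program.hip_r[i]),
            (program.knee_l[i], program.knee_r[i]),
            (program.ankle_l[i], program.ankle_r[i]), i)
        for j, name in enumerate(labels):
            positions[i, j] = markers[name]
        truths[i] = truth
    trial = MarkerTrial(labels, positions, program.rate)
    series = JointAngleSeries(truths, program.rate)
    return trial, series


def make_static_trial(subject: SyntheticSubject, n_frames: int = 10,
                      rate: float = 100.0) -> MarkerTrial:
    """Neutral standing pose (all joint angles zero) replicated
    ``n_frames`` times."""
    trial, _ = _render(subject, MotionProgram.neutral(n_frames, rate))
    return trial


def make_dynamic_trial(subject: SyntheticSubject, program: MotionProgram):
    """Render a motion program; returns (MarkerTrial, ground-truth
    JointAngleSeries).  Deterministic given the program."""
    return _render(subject, program)


def add_noise(trial: MarkerTrial, sd: float, seed: int = 0) -> MarkerTrial:
    """Add i.i.d. zero-mean Gaussian displacement (mm) per marker, frame
    and axis.  ``sd = 0`` returns an identical copy."""
    if sd < 0:
        raise ValidationError(f"noise sd must be >= 0, got {sd}")
    if sd == 0:
        return trial.copy()
    rng = np.random.default_rng(seed)
    noisy = trial.positions + rng.normal(0.0, sd, trial.positions.shape)
    return MarkerTrial(list(trial.labels), noisy, trial.rate, trial.missing.copy())
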