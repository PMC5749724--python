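"""Per-frame Conventional Gait Model kinematics.

The model is direct and hierarchical: pelvis frame from the ASIS/sacrum
markers; hip joint centers by regression (Davis chord of the original
model, or Harrington); knee and ankle joint centers by the chord
function (a Rodrigues-rotation construction in the plane of the proximal
center, the lateral marker and the wand marker); segment frames built
proximal-to-distal; joint angles extracted as Y-X-Z Cardan angles
(flexion, abduction, rotation) using the two-argument arctangent
throughout, so flexion beyond 90 degrees is resolved correctly.

Axis convention: every segment frame is x-anterior, y-left, z-up/proximal,
right-handed.  Left-side abduction and rotation are negated on output so
adduction and internal rotation are positive bilaterally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (ConfigurationError, GeometryError, ValidationError)
from .io_formats import MarkerTrial, SubjectMeasurements
from .series import CHANNELS, N_CHANNELS, SEGMENTS, JointAngleSeries

__all__ = [
    "SegmentFrame", "HipRegressionParams", "HarringtonCoefficients",
    "KinematicsOptions", "FrameResult",
    "chord_joint_center", "rodrigues_rotate", "pelvis_frame",
    "hip_joint_centers", "hip_centers_harrington", "knee_center_medial",
    "segment_frames", "cardan_angles", "compose_cardan", "wrap_degrees",
    "frame_kinematics", "process_trial",
]

_EPS = 1e-12


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _EPS:
        raise GeometryError(f"degenerate {what}: zero length")
    return v / n


def wrap_degrees(a):
    """Wrap angles to the half-open interval (-180, 180]."""
    r = np.asarray(a, dtype=np.float64) % 360.0
    r = np.where(r > 180.0, r - 360.0, r)
    return float(r) if np.isscalar(a) or np.ndim(a) == 0 else r


# ---------------------------------------------------------------------------
# segment frames


@dataclass
class SegmentFrame:
    """A rigid segment pose: origin (mm) plus orthonormal right-handed
    axes x (anterior), y (subject's left), z (up/proximal)."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        for a in (self.x, self.y, self.z):
            if abs(np.linalg.norm(a) - 1.0) > 1e-9:
                raise GeometryError("segment frame axes must be unit length")
        if (abs(self.x @ self.y) > 1e-9 or abs(self.x @ self.z) > 1e-9
                or abs(self.y @ self.z) > 1e-9):
            raise GeometryError("segment frame axes must be orthogonal")
        if np.linalg.norm(np.cross(self.x, self.y) - self.z) > 1e-9:
            raise GeometryError("segment frame must be right-handed (x cross y = z)")

    @classmethod
    def identity(cls) -> "SegmentFrame":
        return cls(np.zeros(3), np.array([1.0, 0, 0]),
                   np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))

    @classmethod
    def from_rotation(cls, R: np.ndarray, origin=(0.0, 0.0, 0.0)) -> "SegmentFrame":
        R = np.asarray(R, dtype=np.float64)
        return cls(np.asarray(origin, dtype=np.float64), R[:, 0], R[:, 1], R[:, 2])

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with the axes as columns."""
        return np.column_stack([self.x, self.y, self.z])

    def as_array(self) -> np.ndarray:
        """(4, 3): origin then x, y, z rows — the axes-archive layout."""
        return np.stack([self.origin, self.x, self.y, self.z])


# ---------------------------------------------------------------------------
# hip regression parameters


@dataclass(frozen=True)
class HarringtonCoefficients:
    """Linear-form coefficients (mm) for the Harrington hip regression:
    anterior = a1*PD + b1; vertical = a2*PW + c2*LL + b2;
    lateral = a3*PD + c3*PW + b3 (toward the respective side)."""

    a1: float = -0.24
    b1: float = -9.9
    a2: float = -0.16
    c2: float = -0.04
    b2: float = -7.1
    a3: float = 0.28
    c3: float = 0.16
    b3: float = 7.9


@dataclass(frozen=True)
class HipRegressionParams:
    """Davis constants (C = c_slope*LL + c_intercept, offset angles theta
    and beta in radians, AT default = at_slope*LL + at_intercept) plus the
    Harrington coefficient table.  All overridable from config."""

    c_slope: float = 0.115
    c_intercept: float = -15.3
    theta: float = 0.496
    beta: float = 0.314
    at_slope: float = 0.1288
    at_intercept: float = -48.56
    harrington: HarringtonCoefficients | None = field(
        default_factory=HarringtonCoefficients)

    def validate(self) -> "HipRegressionParams":
        for name in ("theta", "beta"):
            v = getattr(self, name)
            if not 0.0 < v < math.pi / 2:
                raise ValidationError(
                    f"hip regression angle {name} must lie in (0, pi/2); got {v}")
        return self

    def at_default(self, leg_length: float) -> float:
        return self.at_slope * leg_length + self.at_intercept

    def scaled(self, k: float) -> "HipRegressionParams":
        """Scale every millimetre-valued constant (the intercepts) by ``k``.

        Slopes and angles are dimensionless and unchanged.  This is what
        makes the whole model scale-invariant: scaling markers,
        measurements and the mm intercepts together scales every joint
        center by ``k`` and leaves every angle untouched.
        """
        h = self.harrington
        if h is not None:
            h = replace(h, b1=h.b1 * k, b2=h.b2 * k, b3=h.b3 * k)
        return replace(self, c_intercept=self.c_intercept * k,
                       at_intercept=self.at_intercept * k, harrington=h)


@dataclass
class KinematicsOptions:
    """Processing options.

    hip_method: "davis" (chord-era regression) or "harrington".
    knee_method: "chord" or "medial" (medial knee marker used per frame
    when present, chord otherwise).
    progression_axis: lab direction of walking progression for the foot
    progression angle.
    lab_frame: reference frame for pelvis angles and foot progression;
    identity by default.  Supplying a rotated lab frame makes the
    lab-referenced outputs equivariant under global rotations.
    """

    hip_method: str = "davis"
    knee_method: str = "chord"
    progression_axis: tuple = (1.0, 0.0, 0.0)
    lab_frame: SegmentFrame | None = None
    store_axes: bool = False
    params: HipRegressionParams = field(default_factory=HipRegressionParams)

    def __post_init__(self) -> None:
        if self.hip_method not in ("davis", "harrington"):
            raise ValidationError(f"unknown hip_method {self.hip_method!r}")
        if self.knee_method not in ("chord", "medial"):
            raise ValidationError(f"unknown knee_method {self.knee_method!r}")
        self.params.validate()

    @property
    def lab(self) -> SegmentFrame:
        return self.lab_frame if self.lab_frame is not None else SegmentFrame.identity()


# ---------------------------------------------------------------------------
# geometric constructions


def rodrigues_rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``v`` about the unit ``axis`` by ``angle`` (radians)."""
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1.0 - c)


def chord_joint_center(prox_center, lateral_marker, wand_marker,
                       offset: float, joint: str = "joint") -> np.ndarray:
    """Chord-function joint center.

    Returns the unique point JC in the plane of (P, L, W) with
    |JC - L| = offset and a right angle at JC between P and L, on the
    opposite side of the P-L line from the wand marker W.  Constructed by
    rotating P about the plane normal through twice the chord angle
    arccos(offset/|P-L|) around the midpoint of P and L.
    """
    P = np.asarray(prox_center, dtype=np.float64)
    L = np.asarray(lateral_marker, dtype=np.float64)
    W = np.asarray(wand_marker, dtype=np.float64)
    d = np.linalg.norm(P - L)
    if not offset > 0:
        raise GeometryError(f"{joint}: chord offset must be positive, got {offset}")
    if offset >= d:
        raise GeometryError(
            f"{joint}: measurement exceeds segment length "
            f"(offset {offset:.3f} mm >= marker distance {d:.3f} mm)")
    n = np.cross(W - L, P - L)
    nn = np.linalg.norm(n)
    if nn < _EPS * max(d, 1.0) * max(np.linalg.norm(W - L), 1.0):
        raise GeometryError(
            f"{joint}: proximal center, lateral marker and wand marker are "
            "collinear; chord plane is degenerate")
    n = n / nn
    m = 0.5 * (P + L)
    theta = math.acos(offset / d)
    return m + rodrigues_rotate(P - m, n, 2.0 * theta)


def pelvis_frame(LASI, RASI, SACR) -> SegmentFrame:
    """Pelvis segment frame: origin mid-ASIS, y toward LASI, x anterior
    (away from the sacrum, orthogonalized), z up."""
    LASI = np.asarray(LASI, dtype=np.float64)
    RASI = np.asarray(RASI, dtype=np.float64)
    SACR = np.asarray(SACR, dtype=np.float64)
    origin = 0.5 * (LASI + RASI)
    sep = LASI - RASI
    if np.linalg.norm(sep) < _EPS:
        raise GeometryError("degenerate pelvis: LASI and RASI coincide")
    y = sep / np.linalg.norm(sep)
    front = origin - SACR
    front_perp = front - (front @ y) * y
    if np.linalg.norm(front_perp) < _EPS:
        raise GeometryError(
            "degenerate pelvis: sacrum marker collinear with the ASIS line")
    x = front_perp / np.linalg.norm(front_perp)
    z = np.cross(x, y)
    return SegmentFrame(origin, x, y, z)


def hip_joint_centers(pelvis: SegmentFrame, meas: SubjectMeasurements,
                      calib, params: HipRegressionParams | None = None):
    """Hip joint centers from the Davis-style regression.

    ``calib`` supplies the resolved inter-ASIS distance and per-side
    ASIS-trochanter distances (measured or defaulted).  The displacement
    in pelvis coordinates is anterior u = C cos(theta) sin(beta) -
    (AT + mr) cos(beta), vertical w = -C cos(theta) cos(beta) -
    (AT + mr) sin(beta) (always below the ASIS plane) and lateral
    |C sin(theta) - IAD/2| toward the respective side.
    """
    params = (params or HipRegressionParams()).validate()
    if calib is None:
        raise ValidationError("hip_joint_centers requires a static calibration")
    LL = meas.mean_leg_length
    C = params.c_slope * LL + params.c_intercept
    aa = calib.inter_asis_effective / 2.0
    mr = meas.marker_radius
    ct, st = math.cos(params.theta), math.sin(params.theta)
    cb, sb = math.cos(params.beta), math.sin(params.beta)
    v = aa - C * st  # lateral magnitude, toward the respective side
    out = []
    for at, sgn in ((calib.resolved_at_left, +1.0),
                    (calib.resolved_at_right, -1.0)):
        if at is None:
            raise ValidationError("calibration did not resolve the AT distance")
        u = C * ct * sb - (at + mr) * cb
        w = -C * ct * cb - (at + mr) * sb
        out.append(pelvis.origin + u * pelvis.x + sgn * v * pelvis.y
                   + w * pelvis.z)
    return out[0], out[1]


def hip_centers_harrington(LASI, RASI, LPSI, RPSI, meas: SubjectMeasurements,
                           params: HipRegressionParams | None = None):
    """Harrington hip joint centers from pelvis depth/width and leg length."""
    params = (params or HipRegressionParams()).validate()
    h = params.harrington
    if h is None:
        raise ConfigurationError(
            "Harrington hip method selected but no coefficient table is "
            "configured")
    LASI = np.asarray(LASI, dtype=np.float64)
    RASI = np.asarray(RASI, dtype=np.float64)
    mid_psis = 0.5 * (np.asarray(LPSI, dtype=np.float64)
                      + np.asarray(RPSI, dtype=np.float64))
    pelvis = pelvis_frame(LASI, RASI, mid_psis)
    PW = float(np.linalg.norm(LASI - RASI))
    PD = float(np.linalg.norm(pelvis.origin - mid_psis))
    LL = meas.mean_leg_length
    ant = h.a1 * PD + h.b1
    vert = h.a2 * PW + h.c2 * LL + h.b2
    lat = h.a3 * PD + h.c3 * PW + h.b3
    left = pelvis.origin + ant * pelvis.x + lat * pelvis.y + vert * pelvis.z
    right = pelvis.origin + ant * pelvis.x - lat * pelvis.y + vert * pelvis.z
    return left, right


def knee_center_medial(KNE, KNM):
    """Medial-marker knee center: midpoint of the lateral and medial knee
    markers, with the mediolateral axis direction from the midpoint to the
    medial marker."""
    KNE = np.asarray(KNE, dtype=np.float64)
    KNM = np.asarray(KNM, dtype=np.float64)
    if np.linalg.norm(KNE - KNM) < _EPS:
        raise GeometryError("medial and lateral knee markers coincide")
    jc = 0.5 * (KNE + KNM)
    axis = _unit(KNM - jc, "knee mediolateral axis")
    return jc, axis


# ---------------------------------------------------------------------------
# per-side segment frames


@dataclass
class SideFrames:
    femur: SegmentFrame
    tibia: SegmentFrame
    foot: SegmentFrame
    kjc: np.ndarray
    ajc: np.ndarray


def _long_frame(z_dir: np.ndarray, lateral_marker: np.ndarray,
                jc: np.ndarray, origin: np.ndarray, side: str,
                what: str) -> SegmentFrame:
    """Femur/tibia frame: z along the proximal direction, provisional y
    the mediolateral direction pointing to the subject's left."""
    z = _unit(z_dir, f"{what} long axis")
    if side == "L":
        y_prov = _unit(lateral_marker - jc, f"{what} mediolateral direction")
    else:
        y_prov = _unit(jc - lateral_marker, f"{what} mediolateral direction")
    x = np.cross(y_prov, z)
    x = _unit(x, f"{what} anterior axis")
    y = np.cross(z, x)
    return SegmentFrame(origin, x, y, z)


def segment_frames(markers: dict, hjc: np.ndarray, meas: SubjectMeasurements,
                   calib, side: str,
                   options: KinematicsOptions | None = None) -> SideFrames:
    """Femur, tibia and foot frames for one side from this frame's markers.

    ``markers`` holds the side's THI/KNE/TIB/ANK/TOE (KNM optional, HEE
    accepted but unused).  Changing the ankle width can only move the
    ankle joint center and hence the tibia and foot frames; the knee
    center and femur frame depend on knee width and the hip center alone.
    """
    options = options or KinematicsOptions()
    mr = meas.marker_radius
    if side == "L":
        kw, aw = meas.left_knee_width, meas.left_ankle_width
    else:
        kw, aw = meas.right_knee_width, meas.right_ankle_width

    KNE, THI = markers["KNE"], markers["THI"]
    KNM = markers.get("KNM")
    if options.knee_method == "medial" and KNM is not None:
        kjc, _ = knee_center_medial(KNE, KNM)
    else:
        kjc = chord_joint_center(hjc, KNE, THI, kw / 2.0 + mr,
                                 joint=f"{side} knee")
    femur = _long_frame(hjc - kjc, KNE, kjc, hjc, side, f"{side} femur")

    ANK, TIB = markers["ANK"], markers["TIB"]
    ajc = chord_joint_center(kjc, ANK, TIB, aw / 2.0 + mr,
                             joint=f"{side} ankle")
    tibia = _long_frame(kjc - ajc, ANK, ajc, kjc, side, f"{side} tibia")

    TOE = markers["TOE"]
    fx = _unit(np.asarray(TOE, dtype=np.float64) - ajc, f"{side} foot axis")
    fy = np.cross(tibia.z, fx)
    if np.linalg.norm(fy) < _EPS:
        raise GeometryError(f"{side} foot axis parallel to the tibia long axis")
    fy = fy / np.linalg.norm(fy)
    fz = np.cross(fx, fy)
    foot = SegmentFrame(ajc, fx, fy, fz)
    return SideFrames(femur, tibia, foot, kjc, ajc)


# ---------------------------------------------------------------------------
# Cardan angles


def compose_cardan(alpha: float, beta: float, gamma: float,
                   degrees: bool = True) -> np.ndarray:
    """Rotation matrix Ry(alpha) @ Rx(beta) @ Rz(gamma) — the Y-X-Z
    (flexion, abduction, rotation) sequence; columns are the distal axes
    expressed in the proximal frame."""
    if degrees:
        alpha, beta, gamma = map(math.radians, (alpha, beta, gamma))
    ca, sa = math.cos(alpha), math.sin(alpha)
    cb, sb = math.cos(beta), math.sin(beta)
    cg, sg = math.cos(gamma), math.sin(gamma)
    Ry = np.array([[ca, 0, sa], [0, 1, 0], [-sa, 0, ca]])
    Rx = np.array([[1, 0, 0], [0, cb, -sb], [0, sb, cb]])
    Rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return Ry @ Rx @ Rz


def cardan_angles(prox: SegmentFrame, dist: SegmentFrame) -> tuple[float, float, float]:
    """Y-X-Z Cardan angles (degrees) of ``dist`` relative to ``prox``.

    With M(i, j) the direction cosines between proximal axis i and distal
    axis j, the decomposition M = Ry(a) Rx(b) Rz(g) gives
    a = atan2(M(x,z), M(z,z)), b = atan2(-M(y,z), hypot(M(y,x), M(y,y))),
    g = atan2(M(y,x), M(y,y)) — two-argument arctangents only, so flexion
    and rotation are correct over the full (-180, 180] range.
    """
    M = np.stack([prox.x, prox.y, prox.z]) @ np.stack([dist.x, dist.y, dist.z]).T
    alpha = math.atan2(M[0, 2], M[2, 2])
    beta = math.atan2(-M[1, 2], math.hypot(M[1, 0], M[1, 1]))
    gamma = math.atan2(M[1, 0], M[1, 1])
    return (math.degrees(alpha), math.degrees(beta), math.degrees(gamma))


# ---------------------------------------------------------------------------
# frame orchestrator


_SIDE_MARKERS = ("THI", "KNE", "TIB", "ANK", "TOE")

_CH = {name: i for i, name in enumerate(CHANNELS)}


@dataclass
class FrameResult:
    angles: np.ndarray
    valid_pelvis: bool
    valid_left: bool
    valid_right: bool
    diagnostics: list[str]
    axes: np.ndarray | None = None


def _pelvis_markers(markers: dict):
    LASI, RASI = markers.get("LASI"), markers.get("RASI")
    SACR = markers.get("SACR")
    if SACR is None:
        LPSI, RPSI = markers.get("LPSI"), markers.get("RPSI")
        if LPSI is not None and RPSI is not None:
            SACR = 0.5 * (np.asarray(LPSI, dtype=np.float64)
                          + np.asarray(RPSI, dtype=np.float64))
    return LASI, RASI, SACR


def _foot_progression(foot: SegmentFrame, options: KinematicsOptions) -> float:
    lab = options.lab
    a = np.asarray(options.progression_axis, dtype=np.float64)
    a_h = a - (a @ lab.z) * lab.z
    a_h = _unit(a_h, "progression axis")
    f = foot.x
    f_h = f - (f @ lab.z) * lab.z
    if np.linalg.norm(f_h) < _EPS:
        return math.nan
    f_h = f_h / np.linalg.norm(f_h)
    return math.degrees(math.atan2(lab.z @ np.cross(a_h, f_h), a_h @ f_h))


def frame_kinematics(markers: dict, calib, meas: SubjectMeasurements | None = None,
                     options: KinematicsOptions | None = None) -> FrameResult:
    """Compute one frame's joint-angle record.

    Never raises per frame: frames with missing required markers or
    degenerate geometry yield flagged-invalid records with diagnostics.
    Left-side abduction/rotation are negated; ankle flexion and rotation
    have the static offsets subtracted; all angles wrapped to (-180, 180].
    """
    options = options or KinematicsOptions()
    meas = meas if meas is not None else calib.measurements
    angles = np.full(N_CHANNELS, np.nan)
    diags: list[str] = []
    axes = np.full((len(SEGMENTS), 4, 3), np.nan) if options.store_axes else None

    LASI, RASI, SACR = _pelvis_markers(markers)
    if LASI is None or RASI is None or SACR is None:
        missing = [n for n, v in (("LASI", LASI), ("RASI", RASI),
                                  ("SACR/LPSI+RPSI", SACR)) if v is None]
        diags.append(f"pelvis markers missing: {missing}")
        return FrameResult(angles, False, False, False, diags, axes)
    try:
        pelvis = pelvis_frame(LASI, RASI, SACR)
    except GeometryError as e:
        diags.append(f"geometry: pelvis: {e}")
        return FrameResult(angles, False, False, False, diags, axes)

    lab = options.lab
    angles[0:3] = wrap_degrees(np.asarray(cardan_angles(lab, pelvis)))
    if axes is not None:
        axes[SEGMENTS.index("Pelvis")] = pelvis.as_array()

    if options.hip_method == "harrington":
        LPSI, RPSI = markers.get("LPSI"), markers.get("RPSI")
        if LPSI is None or RPSI is None:
            diags.append("harrington hip method requires LPSI and RPSI markers")
            return FrameResult(angles, True, False, False, diags, axes)
        hjc_l, hjc_r = hip_centers_harrington(LASI, RASI, LPSI, RPSI, meas,
                                              options.params)
    else:
        hjc_l, hjc_r = hip_joint_centers(pelvis, meas, calib, options.params)

    valid = {"L": False, "R": False}
    for side, hjc in (("L", hjc_l), ("R", hjc_r)):
        side_markers = {}
        absent = []
        for key in _SIDE_MARKERS + ("KNM", "HEE"):
            v = markers.get(side + key)
            side_markers[key] = v
            if v is None and key in _SIDE_MARKERS:
                absent.append(side + key)
        if absent:
            diags.append(f"{side}: markers missing: {absent}")
            continue
        try:
            frames = segment_frames(side_markers, hjc, meas, calib, side, options)
        except GeometryError as e:
            diags.append(f"geometry: {side}: {e}")
            continue
        hip = list(cardan_angles(pelvis, frames.femur))
        knee = list(cardan_angles(frames.femur, frames.tibia))
        ankle = list(cardan_angles(frames.tibia, frames.foot))
        if side == "L":
            for trip in (hip, knee, ankle):
                trip[1] = -trip[1]
                trip[2] = -trip[2]
        off = (calib.ankle_offset_left if side == "L"
               else calib.ankle_offset_right)
        ankle[0] -= off[0]
        ankle[2] -= off[1]
        fp = _foot_progression(frames.foot, options)
        angles[_CH[f"{side}Hip_X"]:_CH[f"{side}Hip_X"] + 3] = hip
        angles[_CH[f"{side}Knee_X"]:_CH[f"{side}Knee_X"] + 3] = knee
        angles[_CH[f"{side}Ankle_X"]:_CH[f"{side}Ankle_X"] + 3] = ankle
        angles[_CH[f"{side}FootProgress"]] = fp
        valid[side] = True
        if axes is not None:
            axes[SEGMENTS.index(f"{side}Femur")] = frames.femur.as_array()
            axes[SEGMENTS.index(f"{side}Tibia")] = frames.tibia.as_array()
            axes[SEGMENTS.index(f"{side}Foot")] = frames.foot.as_array()

    mask = ~np.isnan(angles)
    angles[mask] = wrap_degrees(angles[mask])
    return FrameResult(angles, True, valid["L"], valid["R"], diags, axes)


def process_trial(trial: MarkerTrial, calib,
                  options: KinematicsOptions | None = None,
                  n_workers: int = 1) -> JointAngleSeries:
    """Run frame_kinematics over a dynamic trial.

    Output is bit-identical for every worker count; see parallel_exec.
    """
    from . import parallel_exec  # deferred: parallel_exec is generic
    options = options or KinematicsOptions()
    results = parallel_exec.map_frames(trial, calib, options, n_workers)
    n = trial.n_frames
    angles = np.stack([r.angles for r in results]) if n else np.zeros((0, N_CHANNELS))
    axes = None
    if options.store_axes and n:
        axes = np.stack([r.axes for r in results])
    diags = [f"frame {i}: {d}" for i, r in enumerate(results)
             for d in r.diagnostics]
    return JointAngleSeries(
        angles, trial.rate,
        valid_pelvis=np.array([r.valid_pelvis for r in results], dtype=bool),
        valid_left=np.array([r.valid_left for r in results], dtype=bool),
        valid_right=np.array([r.valid_right for r in results], dtype=bool),
        axes=axes, diagnostics=diags)
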