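"""Static-trial calibration.

A short standing trial is averaged once per subject into constants that
every dynamic frame then consumes: the measured inter-ASIS distance, the
per-side ankle offset angles (mean static ankle flexion/rotation,
computed with offsets zero) and the resolved ASIS-trochanter distances
(measured, or the Davis default).  The computation is sequential by
contract — static trials are short and their averaging step does not
benefit from the frame-parallel path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict

import numpy as np

from .cgm_core import KinematicsOptions, frame_kinematics
from .errors import CalibrationError
from .io_formats import MarkerTrial, SubjectMeasurements

__all__ = ["StaticCalibration", "run_static", "REQUIRED_MARKERS"]

#: Markers a frame must carry to participate in the calibration averages.
REQUIRED_MARKERS = (
    "LASI", "RASI",
    "LTHI", "LKNE", "LTIB", "LANK", "LTOE",
    "RTHI", "RKNE", "RTIB", "RANK", "RTOE",
)


@dataclass
class StaticCalibration:
    """Trial-averaged constants acting as inputs to dynamic processing.

    ``measurements`` is the effective snapshot: the subject measurements
    with the inter-ASIS distance and AT distances resolved, frozen so
    that recomputation is deterministic.
    """

    inter_asis_measured: float
    inter_asis_effective: float
    ankle_offset_left: tuple
    ankle_offset_right: tuple
    resolved_at_left: float
    resolved_at_right: float
    measurements: SubjectMeasurements
    n_frames_used: int

    def to_json(self, path) -> None:
        payload = {
            "inter_asis_measured": self.inter_asis_measured,
            "inter_asis_effective": self.inter_asis_effective,
            "ankle_offset_left": list(self.ankle_offset_left),
            "ankle_offset_right": list(self.ankle_offset_right),
            "resolved_at_left": self.resolved_at_left,
            "resolved_at_right": self.resolved_at_right,
            "n_frames_used": self.n_frames_used,
            "measurements": asdict(self.measurements),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StaticCalibration":
        with open(path) as fh:
            payload = json.load(fh)
        meas = SubjectMeasurements(**payload.pop("measurements"))
        payload["ankle_offset_left"] = tuple(payload["ankle_offset_left"])
        payload["ankle_offset_right"] = tuple(payload["ankle_offset_right"])
        return cls(measurements=meas, **payload)


def _sacrum_available(trial: MarkerTrial) -> bool:
    return trial.has("SACR") or (trial.has("LPSI") and trial.has("RPSI"))


def run_static(static: MarkerTrial, meas: SubjectMeasurements,
               options: KinematicsOptions | None = None) -> StaticCalibration:
    """Compute a StaticCalibration from a standing trial.

    Frames with any required marker missing are dropped from the
    averages.  Ankle offsets are the arithmetic mean (in degrees) of the
    per-frame static ankle flexion and rotation computed with offsets
    zero; the abduction component is never offset.
    """
    meas.validate()
    options = options or KinematicsOptions()

    absent = [m for m in REQUIRED_MARKERS if not static.has(m)]
    if not _sacrum_available(static):
        absent.append("SACR (or LPSI+RPSI)")
    if options.hip_method == "harrington":
        absent += [m for m in ("LPSI", "RPSI") if not static.has(m)]
    if absent:
        raise CalibrationError(
            f"static trial is missing required markers: {sorted(set(absent))}")

    needed = list(REQUIRED_MARKERS)
    if static.has("SACR"):
        needed.append("SACR")
    else:
        needed += ["LPSI", "RPSI"]
    idx = [static.labels.index(m) for m in needed]
    valid = ~static.missing[:, idx].any(axis=1)
    if not valid.any():
        raise CalibrationError("static trial has no frame with all required markers")

    lasi = static.marker("LASI")[valid]
    rasi = static.marker("RASI")[valid]
    inter_asis_measured = float(np.mean(np.linalg.norm(lasi - rasi, axis=1)))

    inter_asis_effective = (meas.inter_asis_distance
                            if meas.inter_asis_distance is not None
                            else inter_asis_measured)
    at_default = options.params.at_default(meas.mean_leg_length)
    resolved_at_left = (meas.left_asis_trochanter
                        if meas.left_asis_trochanter is not None else at_default)
    resolved_at_right = (meas.right_asis_trochanter
                         if meas.right_asis_trochanter is not None else at_default)

    snapshot = replace(meas,
                       inter_asis_distance=inter_asis_effective,
                       left_asis_trochanter=resolved_at_left,
                       right_asis_trochanter=resolved_at_right)

    zero = StaticCalibration(
        inter_asis_measured=inter_asis_measured,
        inter_asis_effective=inter_asis_effective,
        ankle_offset_left=(0.0, 0.0), ankle_offset_right=(0.0, 0.0),
        resolved_at_left=resolved_at_left, resolved_at_right=resolved_at_right,
        measurements=snapshot, n_frames_used=int(valid.sum()))

    lflex, lrot, rflex, rrot = [], [], [], []
    diagnostics: list[str] = []
    for i in np.flatnonzero(valid):  # sequential by contract
        rec = frame_kinematics(static.frame_markers(i), zero, options=options)
        diagnostics.extend(rec.diagnostics)
        if rec.valid_left:
            lflex.append(rec.angles[15])   # LAnkle_X
            lrot.append(rec.angles[17])    # LAnkle_Z
        if rec.valid_right:
            rflex.append(rec.angles[18])   # RAnkle_X
            rrot.append(rec.angles[20])    # RAnkle_Z
    if not lflex or not rflex:
        side = "left" if not lflex else "right"
        detail = f" ({diagnostics[0]})" if diagnostics else ""
        raise CalibrationError(
            f"static trial produced no valid {side}-side ankle frames{detail}")

    return replace(zero,
                   ankle_offset_left=(float(np.mean(lflex)), float(np.mean(lrot))),
                   ankle_offset_right=(float(np.mean(rflex)), float(np.mean(rrot))))
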