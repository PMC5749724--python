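"""On-disk representations: marker trials (C3D and a text dialect), VSK
subject measurements, angle tables and compressed angle archives.

All positions are lab-frame millimetres after loading; metre-unit C3D
files are converted on read.  Marker names follow Plug-in-Gait
conventions (LASI, RASI, LPSI/RPSI or SACR, LTHI, LKNE, LTIB, LANK,
LHEE, LTOE and right-side mirrors); an alias map translates nonstandard
names on read.
"""

from __future__ import annotations

import csv
import io
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np

from . import _c3d
from .errors import FormatError, ValidationError
from .series import CHANNELS, N_CHANNELS, SEGMENTS, JointAngleSeries

__all__ = [
    "MarkerTrial", "SubjectMeasurements",
    "read_c3d", "write_c3d", "read_marker_csv", "write_marker_csv",
    "read_vsk", "write_vsk", "write_angles", "read_angles",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MarkerTrial:
    """Labelled 3-D marker trajectories.

    ``positions`` is (n_frames, n_markers, 3) in millimetres, lab frame;
    ``missing`` flags samples that must not be consumed (their position
    values are undefined).
    """

    labels: list[str]
    positions: np.ndarray
    rate: float = 100.0
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ValidationError(f"duplicate marker labels: {dupes}")
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (len(self.labels), 3):
            raise ValidationError(
                f"positions must be (n_frames, {len(self.labels)}, 3); "
                f"got {self.positions.shape}")
        if not self.rate > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.rate}")
        if self.missing is None:
            self.missing = np.zeros(self.positions.shape[:2], dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        self._index = {name: i for i, name in enumerate(self.labels)}

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def has(self, label: str) -> bool:
        return label in self._index

    def marker(self, label: str) -> np.ndarray:
        try:
            return self.positions[:, self._index[label], :]
        except KeyError:
            raise ValidationError(f"trial has no marker {label!r}") from None

    def frame_markers(self, i: int) -> dict[str, np.ndarray | None]:
        """Marker positions for frame ``i``; missing samples map to None."""
        out: dict[str, np.ndarray | None] = {}
        for j, name in enumerate(self.labels):
            out[name] = None if self.missing[i, j] else self.positions[i, j]
        return out

    def copy(self) -> "MarkerTrial":
        return MarkerTrial(list(self.labels), self.positions.copy(),
                           self.rate, self.missing.copy())

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "MarkerTrial":
        """Apply a rigid motion ``x -> R x + t`` to every marker."""
        R = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64)
        pos = self.positions @ R.T + t
        return MarkerTrial(list(self.labels), pos, self.rate, self.missing.copy())

    def scaled(self, k: float) -> "MarkerTrial":
        return MarkerTrial(list(self.labels), self.positions * k,
                           self.rate, self.missing.copy())


@dataclass(frozen=True)
class SubjectMeasurements:
    """Anthropometric scalars parameterizing joint-center construction.

    All lengths in millimetres.  ``sole_delta`` is accepted for
    compatibility but unused by the lower-body model; ``marker_radius``
    enters the chord offsets as width/2 + radius.
    """

    left_leg_length: float
    right_leg_length: float
    left_knee_width: float
    right_knee_width: float
    left_ankle_width: float
    right_ankle_width: float
    inter_asis_distance: float | None = None
    left_asis_trochanter: float | None = None
    right_asis_trochanter: float | None = None
    sole_delta: float = 0.0
    marker_radius: float = 0.0
    subject_id: str = ""

    def validate(self) -> "SubjectMeasurements":
        required = {
            "left_leg_length": self.left_leg_length,
            "right_leg_length": self.right_leg_length,
            "left_knee_width": self.left_knee_width,
            "right_knee_width": self.right_knee_width,
            "left_ankle_width": self.left_ankle_width,
            "right_ankle_width": self.right_ankle_width,
        }
        bad = [k for k, v in required.items() if v is None or not v > 0]
        if bad:
            raise ValidationError(
                f"subject measurements must be strictly positive: {bad}")
        for k in ("inter_asis_distance", "left_asis_trochanter",
                  "right_asis_trochanter"):
            v = getattr(self, k)
            if v is not None and not v > 0:
                raise ValidationError(f"{k} must be strictly positive when given")
        if self.marker_radius < 0:
            raise ValidationError("marker_radius must be non-negative")
        return self

    @property
    def mean_leg_length(self) -> float:
        return 0.5 * (self.left_leg_length + self.right_leg_length)

    def with_offsets(self, ll: float = 0.0, kw: float = 0.0, aw: float = 0.0,
                     at: float = 0.0, iad: float = 0.0) -> "SubjectMeasurements":
        """Apply identical offsets to the left and right measurements.

        AT and IAD offsets require the corresponding baseline to be set
        (callers resolve defaults first).
        """
        kw_fields: dict = {}
        if at:
            if self.left_asis_trochanter is None or self.right_asis_trochanter is None:
                raise ValidationError(
                    "AT offset requires a resolved asis_trochanter baseline")
            kw_fields["left_asis_trochanter"] = self.left_asis_trochanter + at
            kw_fields["right_asis_trochanter"] = self.right_asis_trochanter + at
        if iad:
            if self.inter_asis_distance is None:
                raise ValidationError(
                    "IAD offset requires a resolved inter_asis_distance baseline")
            kw_fields["inter_asis_distance"] = self.inter_asis_distance + iad
        return replace(
            self,
            left_leg_length=self.left_leg_length + ll,
            right_leg_length=self.right_leg_length + ll,
            left_knee_width=self.left_knee_width + kw,
            right_knee_width=self.right_knee_width + kw,
            left_ankle_width=self.left_ankle_width + aw,
            right_ankle_width=self.right_ankle_width + aw,
            **kw_fields,
        )

    def scaled(self, k: float) -> "SubjectMeasurements":
        """Scale every length (marker_radius included) by ``k``."""
        def s(v):
            return None if v is None else v * k
        return replace(
            self,
            left_leg_length=self.left_leg_length * k,
            right_leg_length=self.right_leg_length * k,
            left_knee_width=self.left_knee_width * k,
            right_knee_width=self.right_knee_width * k,
            left_ankle_width=self.left_ankle_width * k,
            right_ankle_width=self.right_ankle_width * k,
            inter_asis_distance=s(self.inter_asis_distance),
            left_asis_trochanter=s(self.left_asis_trochanter),
            right_asis_trochanter=s(self.right_asis_trochanter),
            sole_delta=self.sole_delta * k,
            marker_radius=self.marker_radius * k,
        )


# ---------------------------------------------------------------------------
# C3D


def _normalize_label(raw: str, alias_map: dict[str, str] | None) -> str:
    name = raw.split(":")[-1].strip()
    if alias_map and name in alias_map:
        name = alias_map[name]
    return name


def read_c3d(path, alias_map: dict[str, str] | None = None) -> MarkerTrial:
    """Read the 3-D point section of a C3D file into millimetres.

    Subject prefixes are stripped from labels ("Subj:LASI" -> "LASI");
    residual-flagged points become missing-mask entries.
    """
    if not os.path.exists(path):
        raise FormatError(f"C3D file not found: {path}")
    labels, positions, rate, missing, units = _c3d.read_c3d_raw(path)
    units_l = units.lower()
    if units_l.startswith("m") and not units_l.startswith("mm"):
        positions = positions * 1000.0
    labels = [_normalize_label(s, alias_map) for s in labels]
    return MarkerTrial(labels, positions, rate, missing)


def write_c3d(trial: MarkerTrial, path) -> None:
    """Write a trial as a float-storage C3D file (millimetres)."""
    _c3d.write_c3d(path, trial.labels, trial.positions, trial.rate,
                   trial.missing, units="mm")


# ---------------------------------------------------------------------------
# marker-table text dialect


def write_marker_csv(trial: MarkerTrial, path) -> None:
    """Text dialect: a "# rate=<Hz>" comment, a header row
    ``frame,<name>_X,<name>_Y,<name>_Z,...`` and one row per frame.
    Missing samples are blank cells.  Floats are written with shortest
    round-trip precision, so write -> read is bit-identical.
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# rate={trial.rate!r}\n")
        header = ["frame"]
        for name in trial.labels:
            header += [f"{name}_X", f"{name}_Y", f"{name}_Z"]
        fh.write(",".join(header) + "\n")
        for i in range(trial.n_frames):
            row = [str(i + 1)]
            for j in range(len(trial.labels)):
                if trial.missing[i, j]:
                    row += ["", "", ""]
                else:
                    row += [repr(float(v)) for v in trial.positions[i, j]]
            fh.write(",".join(row) + "\n")


def read_marker_csv(path, alias_map: dict[str, str] | None = None) -> MarkerTrial:
    rate = 100.0
    with open(path, "r", newline="") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if stripped.startswith("rate="):
                try:
                    rate = float(stripped[5:])
                except ValueError:
                    raise FormatError(
                        f"line {k + 1}: invalid rate comment {line!r}") from None
            continue
        body_start = k
        break
    else:
        raise FormatError("marker CSV contains no header row")

    header = next(csv.reader([lines[body_start]]))
    if not header or header[0] != "frame":
        raise FormatError(
            f"line {body_start + 1}: header must start with 'frame'")
    coord_cols = header[1:]
    if len(coord_cols) % 3:
        raise FormatError(
            f"line {body_start + 1}: marker columns must come in _X/_Y/_Z triples")
    labels = []
    for t in range(0, len(coord_cols), 3):
        trip = coord_cols[t:t + 3]
        names = [c.rsplit("_", 1) for c in trip]
        if (len(set(n for n, _ in names)) != 1
                or [s for _, s in names] != ["X", "Y", "Z"]):
            raise FormatError(
                f"line {body_start + 1}: malformed column triple {trip}")
        labels.append(_normalize_label(names[0][0], alias_map))
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate marker columns: {dupes}")

    n_cols = 1 + 3 * len(labels)
    rows = []
    for k in range(body_start + 1, len(lines)):
        if not lines[k].strip():
            continue
        fields = next(csv.reader([lines[k]]))
        if len(fields) != n_cols:
            raise FormatError(
                f"line {k + 1}: expected {n_cols} fields, got {len(fields)}")
        rows.append((k + 1, fields))
    if not rows:
        raise FormatError("marker CSV contains no data rows")

    n, m = len(rows), len(labels)
    positions = np.zeros((n, m, 3))
    missing = np.zeros((n, m), dtype=bool)
    for i, (lineno, fields) in enumerate(rows):
        for j in range(m):
            cells = fields[1 + 3 * j: 4 + 3 * j]
            if any(c.strip() == "" for c in cells):
                missing[i, j] = True
                positions[i, j] = np.nan
                continue
            try:
                positions[i, j] = [float(c) for c in cells]
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-numeric value for marker "
                    f"{labels[j]}") from None
    return MarkerTrial(labels, positions, rate, missing)


# ---------------------------------------------------------------------------
# VSK subject measurements

_VSK_FIELDS = {
    "LeftLegLength": "left_leg_length",
    "RightLegLength": "right_leg_length",
    "LeftKneeWidth": "left_knee_width",
    "RightKneeWidth": "right_knee_width",
    "LeftAnkleWidth": "left_ankle_width",
    "RightAnkleWidth": "right_ankle_width",
    "InterAsisDistance": "inter_asis_distance",
    # Vicon spells it "Trocanter"; accept both.
    "LeftAsisTrocanterDistance": "left_asis_trochanter",
    "RightAsisTrocanterDistance": "right_asis_trochanter",
    "LeftAsisTrochanterDistance": "left_asis_trochanter",
    "RightAsisTrochanterDistance": "right_asis_trochanter",
    "SoleDelta": "sole_delta",
    "LeftSoleDelta": "sole_delta",
    "RightSoleDelta": "sole_delta",
    "MarkerRadius": "marker_radius",
}

_VSK_REQUIRED = ("LeftLegLength", "RightLegLength", "LeftKneeWidth",
                 "RightKneeWidth", "LeftAnkleWidth", "RightAnkleWidth")


def read_vsk(path) -> SubjectMeasurements:
    """Parse subject measurements from a VSK (XML) file.

    Accepts both attribute-style ``<Parameter NAME=.. VALUE=..>`` nodes
    and simple ``<Param name=.. value=..>`` nodes anywhere in the tree.
    """
    try:
        tree = ET.parse(path)
    except (ET.ParseError, OSError) as e:
        raise FormatError(f"cannot parse VSK file {path}: {e}") from None
    raw: dict[str, str] = {}
    for node in tree.iter():
        attrs = {k.upper(): v for k, v in node.attrib.items()}
        if "NAME" in attrs and "VALUE" in attrs:
            raw[attrs["NAME"]] = attrs["VALUE"]
    values: dict[str, float] = {}
    for vsk_name, field_name in _VSK_FIELDS.items():
        if vsk_name in raw:
            try:
                values[field_name] = float(raw[vsk_name])
            except ValueError:
                raise FormatError(
                    f"VSK parameter {vsk_name} is not numeric: "
                    f"{raw[vsk_name]!r}") from None
    missing = [n for n in _VSK_REQUIRED if _VSK_FIELDS[n] not in values]
    if missing:
        raise ValidationError(
            f"VSK file is missing required measurements: {missing}")
    subject_id = ""
    root = tree.getroot()
    if root.tag.upper() in ("KINEMATICMODEL", "VSK") and "MODEL" in (
            k.upper() for k in root.attrib):
        subject_id = next(v for k, v in root.attrib.items()
                          if k.upper() == "MODEL")
    return SubjectMeasurements(subject_id=subject_id, **values).validate()


def write_vsk(meas: SubjectMeasurements, path) -> None:
    """Write measurements as a simple VSK-dialect XML file."""
    root = ET.Element("KinematicModel", MODEL=meas.subject_id or "cgmkin")
    params = ET.SubElement(root, "Parameters")
    seen = set()
    for vsk_name, field_name in _VSK_FIELDS.items():
        if field_name in seen:
            continue
        v = getattr(meas, field_name)
        if v is None:
            continue
        seen.add(field_name)
        ET.SubElement(params, "Parameter", NAME=vsk_name, VALUE=repr(float(v)))
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# angle tables and archives


def write_angles(series: JointAngleSeries, path, payload: str = "angles") -> None:
    """Write a joint-angle series.

    ``.npz`` paths produce a compressed archive of named arrays whose
    payload is selectable: ``"angles"`` stores the angle table only,
    ``"angles+axes"`` additionally stores the per-frame segment frames.
    Any other extension produces a CSV with the fixed 23-channel header
    (axes payload requires the archive container).
    """
    if payload not in ("angles", "angles+axes"):
        raise ValidationError(f"unknown payload selector {payload!r}")
    if series.n_frames == 0:
        raise ValidationError("cannot write an empty angle series")
    if str(path).endswith(".npz"):
        arrays = {
            "channels": np.asarray(CHANNELS),
            "angles": series.angles,
            "rate": np.float64(series.rate),
            "valid_pelvis": series.valid_pelvis,
            "valid_left": series.valid_left,
            "valid_right": series.valid_right,
            "payload": np.asarray(payload),
        }
        if payload == "angles+axes":
            if series.axes is None:
                raise ValidationError(
                    "payload 'angles+axes' requested but the series carries "
                    "no segment frames")
            arrays["segments"] = np.asarray(SEGMENTS)
            arrays["axes"] = series.axes
        np.savez_compressed(path, **arrays)
        return
    if payload == "angles+axes":
        raise ValidationError(
            "payload 'angles+axes' requires an .npz archive path")
    buf = io.StringIO()
    buf.write(f"# rate={series.rate!r}\n")
    buf.write("frame," + ",".join(CHANNELS) + "\n")
    for i in range(series.n_frames):
        row = [str(i + 1)] + [repr(float(v)) for v in series.angles[i]]
        buf.write(",".join(row) + "\n")
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def read_angles(path) -> JointAngleSeries:
    if str(path).endswith(".npz"):
        with np.load(path, allow_pickle=False) as z:
            channels = [str(s) for s in z["channels"]]
            if channels != list(CHANNELS):
                raise FormatError("angle archive has an unexpected channel set")
            axes = z["axes"] if "axes" in z.files else None
            return JointAngleSeries(
                z["angles"], float(z["rate"]),
                valid_pelvis=z["valid_pelvis"], valid_left=z["valid_left"],
                valid_right=z["valid_right"], axes=axes)
    rate = 100.0
    with open(path) as fh:
        lines = [l for l in fh.read().splitlines() if l.strip()]
    start = 0
    if lines and lines[0].startswith("#"):
        stripped = lines[0][1:].strip()
        if stripped.startswith("rate="):
            rate = float(stripped[5:])
        start = 1
    header = lines[start].split(",")
    if header != ["frame"] + list(CHANNELS):
        raise FormatError("angle CSV header does not match the fixed channel order")
    data = []
    for k, line in enumerate(lines[start + 1:], start=start + 2):
        fields = line.split(",")
        if len(fields) != 1 + N_CHANNELS:
            raise FormatError(
                f"line {k}: expected {1 + N_CHANNELS} fields, got {len(fields)}")
        data.append([float(v) for v in fields[1:]])
    angles = np.asarray(data)
    nan = np.isnan(angles)
    from .series import LEFT_CHANNELS, RIGHT_CHANNELS  # local to avoid cycle noise
    return JointAngleSeries(
        angles, rate,
        valid_pelvis=~nan[:, 0:3].any(axis=1),
        valid_left=~nan[:, LEFT_CHANNELS].any(axis=1),
        valid_right=~nan[:, RIGHT_CHANNELS].any(axis=1))
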