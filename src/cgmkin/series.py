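"""Joint-angle series container and the fixed output channel order.

The channel order is part of the on-disk contract: pelvis X/Y/Z, then for
each joint (hip, knee, ankle) the left and right X/Y/Z triples, then the
left and right foot-progression angles — 23 channels in total.  X is
flexion (tilt for the pelvis), Y abduction (obliquity), Z rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

CHANNELS: tuple[str, ...] = (
    "Pelvis_X", "Pelvis_Y", "Pelvis_Z",
    "LHip_X", "LHip_Y", "LHip_Z",
    "RHip_X", "RHip_Y", "RHip_Z",
    "LKnee_X", "LKnee_Y", "LKnee_Z",
    "RKnee_X", "RKnee_Y", "RKnee_Z",
    "LAnkle_X", "LAnkle_Y", "LAnkle_Z",
    "RAnkle_X", "RAnkle_Y", "RAnkle_Z",
    "LFootProgress", "RFootProgress",
)

N_CHANNELS = len(CHANNELS)

#: Segment frames stored in the axes payload, in order.
SEGMENTS: tuple[str, ...] = (
    "Pelvis", "LFemur", "RFemur", "LTibia", "RTibia", "LFoot", "RFoot",
)

PELVIS_SLICE = slice(0, 3)
LEFT_CHANNELS = [3, 4, 5, 9, 10, 11, 15, 16, 17, 21]
RIGHT_CHANNELS = [6, 7, 8, 12, 13, 14, 18, 19, 20, 22]


def channel_index(name: str) -> int:
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise ValidationError(f"unknown angle channel {name!r}") from None


@dataclass
class JointAngleSeries:
    """Per-frame lower-body Cardan angles in degrees.

    ``angles`` is (n_frames, 23) following :data:`CHANNELS`; invalid
    channels hold NaN and are flagged through the per-side validity masks
    (never silent zeros).  ``axes``, when present, is
    (n_frames, 7, 4, 3): per segment the origin followed by the x/y/z unit
    axes, ordered as :data:`SEGMENTS`.
    """

    angles: np.ndarray
    rate: float = 100.0
    valid_pelvis: np.ndarray | None = None
    valid_left: np.ndarray | None = None
    valid_right: np.ndarray | None = None
    axes: np.ndarray | None = None
    diagnostics: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.ndim != 2 or self.angles.shape[1] != N_CHANNELS:
            raise ValidationError(
                f"angle table must be (n_frames, {N_CHANNELS}); "
                f"got {self.angles.shape}")
        n = self.angles.shape[0]
        for attr in ("valid_pelvis", "valid_left", "valid_right"):
            v = getattr(self, attr)
            if v is None:
                v = np.ones(n, dtype=bool)
            setattr(self, attr, np.asarray(v, dtype=bool))

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.angles[:, channel_index(name)]

    @property
    def all_valid(self) -> np.ndarray:
        """Frames where pelvis and both sides are valid."""
        return self.valid_pelvis & self.valid_left & self.valid_right
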