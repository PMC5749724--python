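"""Minimal C3D codec (3-D point section only).

Implements the subset of the public C3D standard needed for marker trials:
the 512-byte header, an Intel-format parameter section with a POINT group
(USED, FRAMES, RATE, SCALE, DATA_START, UNITS, LABELS), and the point data
section.  The writer always stores floating-point samples (POINT:SCALE < 0);
the reader accepts both float and scaled-integer storage.  Analog channels
and event sections are ignored.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError

_BLOCK = 512
_PROC_INTEL = 84  # 83 + 1 per the C3D convention


def _pad_block(buf: bytearray) -> None:
    if len(buf) % _BLOCK:
        buf.extend(b"\x00" * (_BLOCK - len(buf) % _BLOCK))


def _param_record(name: str, group_id: int, elem_size: int, dims: list[int],
                  data: bytes) -> bytes:
    name_b = name.encode("ascii")
    rec = bytearray()
    rec.append(len(name_b))
    rec.append(group_id & 0xFF)
    rec.extend(name_b)
    body = bytearray()
    body.append(elem_size & 0xFF)
    body.append(len(dims))
    body.extend(dims)
    body.extend(data)
    body.append(0)  # description length
    rec.extend(struct.pack("<h", len(body) + 2))  # offset to next record
    rec.extend(body)
    return bytes(rec)


def _group_record(name: str, group_id: int) -> bytes:
    name_b = name.encode("ascii")
    rec = bytearray()
    rec.append(len(name_b))
    rec.append((-group_id) & 0xFF)
    rec.extend(name_b)
    rec.extend(struct.pack("<h", 3))  # offset: desc-length byte + next
    rec.append(0)
    return bytes(rec)


def write_c3d(path, labels: list[str], positions: np.ndarray,
              rate: float, missing: np.ndarray | None = None,
              units: str = "mm") -> None:
    """Write a float-storage C3D file.

    ``positions`` is (n_frames, n_markers, 3) in the units given by
    ``units``; samples flagged in ``missing`` get a negative residual.
    """
    positions = np.asarray(positions, dtype=np.float32)
    n_frames, n_markers = positions.shape[0], positions.shape[1]
    if n_frames < 1:
        raise FormatError("cannot write a C3D file with zero frames")
    if n_frames > 65535:
        raise FormatError("writer supports at most 65535 frames")
    if missing is None:
        missing = np.zeros((n_frames, n_markers), dtype=bool)

    # --- parameter section -------------------------------------------------
    label_width = max(max((len(s) for s in labels), default=4), 4)
    label_data = b"".join(s.ljust(label_width).encode("ascii") for s in labels)
    units_b = units.encode("ascii")

    params = bytearray()
    params.extend(bytes([0x01, 0x50, 0, _PROC_INTEL]))  # nblocks patched below
    params.extend(_group_record("POINT", 1))
    params.extend(_param_record("USED", 1, 2, [], struct.pack("<h", n_markers)))
    params.extend(_param_record("FRAMES", 1, 2, [], struct.pack("<h", min(n_frames, 32767))))
    params.extend(_param_record("RATE", 1, 4, [], struct.pack("<f", float(rate))))
    params.extend(_param_record("SCALE", 1, 4, [], struct.pack("<f", -1.0)))
    params.extend(_param_record("UNITS", 1, -1, [len(units_b)], units_b))
    params.extend(_param_record("LABELS", 1, -1, [label_width, n_markers], label_data))
    data_start_pos = len(params)
    params.extend(_param_record("DATA_START", 1, 2, [], struct.pack("<h", 0)))
    # terminator record (offset 0)
    params.extend(bytes([0, 1]))
    params.extend(struct.pack("<h", 0))
    _pad_block(params)
    n_param_blocks = len(params) // _BLOCK
    params[2] = n_param_blocks
    data_start_block = 2 + n_param_blocks
    # patch DATA_START value: record layout is name(10)+offset(2)+type(1)+ndims(1)+value
    ds_value_off = data_start_pos + 2 + len("DATA_START") + 2 + 2
    params[ds_value_off:ds_value_off + 2] = struct.pack("<h", data_start_block)

    # --- header ------------------------------------------------------------
    header = bytearray(_BLOCK)
    header[0] = 2          # first parameter block
    header[1] = 0x50
    struct.pack_into("<H", header, 2, n_markers)
    struct.pack_into("<H", header, 4, 0)            # analog per frame
    struct.pack_into("<H", header, 6, 1)            # first frame
    struct.pack_into("<H", header, 8, n_frames)     # last frame
    struct.pack_into("<H", header, 10, 10)          # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)        # 3D scale factor
    struct.pack_into("<H", header, 16, data_start_block)
    struct.pack_into("<H", header, 18, 0)           # analog samples per frame
    struct.pack_into("<f", header, 20, float(rate))

    # --- point data --------------------------------------------------------
    frames = np.empty((n_frames, n_markers, 4), dtype="<f4")
    frames[:, :, :3] = positions
    frames[:, :, 3] = np.where(missing, -1.0, 0.0)
    data = bytearray(frames.tobytes())
    _pad_block(data)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(params)
        fh.write(data)


def _read_records(section: bytes):
    """Yield (name, group_id, elem_size, dims, raw_data) parameter records."""
    pos = 4
    while pos < len(section):
        name_len = struct.unpack_from("<b", section, pos)[0]
        group_id = struct.unpack_from("<b", section, pos + 1)[0]
        if name_len == 0:
            break
        name = section[pos + 2: pos + 2 + abs(name_len)].decode("ascii", "replace")
        off_pos = pos + 2 + abs(name_len)
        next_off = struct.unpack_from("<h", section, off_pos)[0]
        if group_id > 0:  # parameter
            p = off_pos + 2
            elem = struct.unpack_from("<b", section, p)[0]
            ndims = section[p + 1]
            dims = list(section[p + 2: p + 2 + ndims])
            count = 1
            for d in dims:
                count *= d
            dp = p + 2 + ndims
            raw = section[dp: dp + count * abs(elem)]
            yield name, group_id, elem, dims, raw
        if next_off == 0:
            break
        pos = off_pos + 2 + next_off - 2


def read_c3d_raw(path):
    """Parse a C3D file.

    Returns (labels, positions (n,m,3) float64, rate, missing mask, units).
    Positions are in the file's own units; the caller normalizes.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < _BLOCK:
        raise FormatError("C3D header: file shorter than one 512-byte block")
    if blob[1] != 0x50:
        raise FormatError("C3D header: missing 0x50 signature byte")
    param_block = blob[0]
    n_markers = struct.unpack_from("<H", blob, 2)[0]
    first_frame = struct.unpack_from("<H", blob, 6)[0]
    last_frame = struct.unpack_from("<H", blob, 8)[0]
    header_scale = struct.unpack_from("<f", blob, 12)[0]
    data_start = struct.unpack_from("<H", blob, 16)[0]
    header_rate = struct.unpack_from("<f", blob, 20)[0]

    poff = (param_block - 1) * _BLOCK
    if poff + 4 > len(blob):
        raise FormatError("C3D parameter section: offset beyond end of file")
    n_param_blocks = blob[poff + 2]
    proc = blob[poff + 3]
    if proc != _PROC_INTEL:
        raise FormatError(
            f"C3D parameter section: unsupported processor type {proc} "
            "(only Intel/PC format is supported)")
    section = blob[poff: poff + max(n_param_blocks, 1) * _BLOCK]

    # first pass: group definitions, to find the POINT group id
    point: dict[str, tuple] = {}
    group_ids: dict[int, str] = {}
    p = 4
    while p < len(section):
        name_len = struct.unpack_from("<b", section, p)[0]
        gid = struct.unpack_from("<b", section, p + 1)[0]
        if name_len == 0:
            break
        name = section[p + 2: p + 2 + abs(name_len)].decode("ascii", "replace")
        off_pos = p + 2 + abs(name_len)
        next_off = struct.unpack_from("<h", section, off_pos)[0]
        if gid < 0:
            group_ids[-gid] = name.upper()
        if next_off == 0:
            break
        p = off_pos + 2 + next_off - 2
    point_gid = next((g for g, n in group_ids.items() if n == "POINT"), None)
    if point_gid is None:
        raise FormatError("C3D parameter section: no POINT group found")

    for name, gid, elem, dims, raw in _read_records(section):
        if gid == point_gid:
            point[name.upper()] = (elem, dims, raw)

    def _scalar(name, fmt, default=None):
        if name not in point:
            return default
        _, _, raw = point[name]
        return struct.unpack_from(fmt, raw, 0)[0]

    used = _scalar("USED", "<h", n_markers)
    rate = _scalar("RATE", "<f", header_rate) or 100.0
    scale = _scalar("SCALE", "<f", header_scale)
    data_start = _scalar("DATA_START", "<h", data_start)
    n_frames = last_frame - first_frame + 1
    frames_param = _scalar("FRAMES", "<h", None)
    if frames_param is not None and frames_param > 0 and n_frames <= 0:
        n_frames = frames_param
    if n_frames <= 0 or used <= 0:
        raise FormatError("C3D point section: trial contains zero frames or markers")

    units = "mm"
    if "UNITS" in point:
        units = point["UNITS"][2].decode("ascii", "replace").strip() or "mm"

    labels = []
    if "LABELS" in point:
        _, dims, raw = point["LABELS"]
        if len(dims) == 2:
            w, cnt = dims
            for i in range(min(cnt, used)):
                labels.append(raw[i * w:(i + 1) * w].decode("ascii", "replace").strip())
    if len(labels) < used:
        labels += [f"M{i:03d}" for i in range(len(labels), used)]

    doff = (data_start - 1) * _BLOCK
    n_vals = n_frames * used * 4
    if scale is None:
        scale = header_scale
    item = 4 if scale < 0 else 2
    if doff < 0 or doff + n_vals * item > len(blob):
        raise FormatError("C3D point section: data shorter than header promises")
    if scale < 0:
        arr = np.frombuffer(blob, dtype="<f4", count=n_vals, offset=doff)
        frames = arr.reshape(n_frames, used, 4).astype(np.float64)
        residual = frames[:, :, 3]
        positions = frames[:, :, :3].copy()
    else:
        arr = np.frombuffer(blob, dtype="<i2", count=n_vals, offset=doff)
        frames = arr.reshape(n_frames, used, 4).astype(np.float64)
        residual = frames[:, :, 3]
        positions = frames[:, :, :3] * scale
    missing = residual < 0
    return labels, positions, float(rate), missing, units
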