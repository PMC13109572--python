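"""Minimal LAS 1.2 reader/writer (point data record format 0).

Coordinates are stored as scaled 32-bit integers with a 1 mm quantum, so a
write/read round trip preserves them to within 0.5 mm. Classification and
return number are carried in the standard format-0 fields. Only the subset
of the format needed for local-frame UAV clouds is implemented; variable
length records are skipped on read and never written.
"""

from __future__ import annotations

import struct

import numpy as np

from .cloud import PointCloud
from .errors import FormatError

_HEADER_FMT = "<4sHHLHH8sBB32s32sHHHLLBHL5L12d"
_HEADER_SIZE = struct.calcsize(_HEADER_FMT)  # 227
_POINT_DTYPE = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
    ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
    ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
])
_SCALE = 0.001


def write_las(pc: PointCloud, path) -> None:
    n = len(pc)
    if n:
        offs = (np.floor(pc.x.min()), np.floor(pc.y.min()), np.floor(pc.z.min()))
        maxs = (pc.x.max(), pc.y.max(), pc.z.max())
        mins = (pc.x.min(), pc.y.min(), pc.z.min())
    else:
        offs, maxs, mins = (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0)
    header = struct.pack(
        _HEADER_FMT,
        b"LASF", 0, 0, 0, 0, 0, b"\0" * 8, 1, 2,
        b"voxfpar".ljust(32, b"\0"), b"voxfpar".ljust(32, b"\0"),
        0, 0, _HEADER_SIZE, _HEADER_SIZE, 0, 0, _POINT_DTYPE.itemsize, n,
        n, 0, 0, 0, 0,
        _SCALE, _SCALE, _SCALE, offs[0], offs[1], offs[2],
        maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2],
    )
    rec = np.zeros(n, dtype=_POINT_DTYPE)
    rec["X"] = np.round((pc.x - offs[0]) / _SCALE).astype(np.int64)
    rec["Y"] = np.round((pc.y - offs[1]) / _SCALE).astype(np.int64)
    rec["Z"] = np.round((pc.z - offs[2]) / _SCALE).astype(np.int64)
    # return number 1 of 1 unless the cloud carries return numbers
    rn = pc.return_number if pc.return_number is not None else np.ones(n, dtype=np.uint8)
    rec["flags"] = (rn & 0x07) | (1 << 3)
    if pc.classification is not None:
        rec["classification"] = pc.classification
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


def read_las(path) -> PointCloud:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER_SIZE:
        raise FormatError(
            f"{path}: truncated LAS header ({len(raw)} bytes, need {_HEADER_SIZE})")
    fields = struct.unpack(_HEADER_FMT, raw[:_HEADER_SIZE])
    if fields[0] != b"LASF":
        raise FormatError(f"{path}: bad signature {fields[0]!r} at offset 0")
    header_size, offset, _n_vlr, fmt, rec_len, n = fields[13:19]
    if fmt != 0:
        raise FormatError(f"{path}: unsupported point format {fmt} (offset 104)")
    if rec_len != _POINT_DTYPE.itemsize:
        raise FormatError(f"{path}: unexpected record length {rec_len} (offset 105)")
    need = offset + n * rec_len
    if len(raw) < need:
        raise FormatError(
            f"{path}: point data truncated at offset {len(raw)} (need {need})")
    scales = fields[24:27]
    offs = fields[27:30]
    rec = np.frombuffer(raw[offset:need], dtype=_POINT_DTYPE)
    return PointCloud(
        x=rec["X"] * scales[0] + offs[0],
        y=rec["Y"] * scales[1] + offs[1],
        z=rec["Z"] * scales[2] + offs[2],
        classification=rec["classification"].copy(),
        return_number=(rec["flags"] & 0x07).astype(np.uint8),
    )
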