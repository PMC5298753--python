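"""Minimal LAS 1.2 reader/writer (point format 0).

Covers exactly what the pipeline needs: planar coordinates at a declared
scale, return numbers and ASPRS classification codes.  Writing always emits
point format 0; reading accepts point formats 0-3 of any LAS 1.x file (the
leading 20 bytes of those record layouts coincide).  Coordinates round-trip
bit-faithfully at the declared scale (default 1 mm).
"""

from __future__ import annotations

import struct

import numpy as np

from grasslidar.pointcloud import PointCloud

_HEADER_FMT = "<4sHH16sBB32s32sHHHIIBHI5I12d"
_HEADER_SIZE = 227
_POINT0_DTYPE = {
    "names": ["X", "Y", "Z", "intensity", "flags", "classification",
              "scan_angle", "user_data", "point_source"],
    "formats": ["<i4", "<i4", "<i4", "<u2", "u1", "u1", "i1", "u1", "<u2"],
    "offsets": [0, 4, 8, 12, 14, 15, 16, 17, 18],
}
_POINT_RECORD_LENGTHS = {0: 20, 1: 28, 2: 26, 3: 34}


def write_las(cloud: PointCloud, path, scale: float = 0.001) -> None:
    """Write a cloud as LAS 1.2 / point format 0."""
    n = len(cloud)
    if n:
        offsets = (float(np.floor(cloud.x.min())),
                   float(np.floor(cloud.y.min())),
                   float(np.floor(cloud.z.min())))
        mins = (cloud.x.min(), cloud.y.min(), cloud.z.min())
        maxs = (cloud.x.max(), cloud.y.max(), cloud.z.max())
    else:
        offsets = (0.0, 0.0, 0.0)
        mins = maxs = (0.0, 0.0, 0.0)

    by_return = [int(np.sum(cloud.return_number == r)) for r in range(1, 6)]
    header = struct.pack(
        _HEADER_FMT,
        b"LASF", 0, 0, b"\0" * 16, 1, 2,
        b"grasslidar".ljust(32, b"\0"), b"grasslidar".ljust(32, b"\0"),
        0, 0, _HEADER_SIZE, _HEADER_SIZE, 0, 0, 20, n, *by_return,
        scale, scale, scale, *offsets,
        maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2])

    rec = np.zeros(n, dtype=_POINT0_DTYPE)
    if n:
        rec["X"] = np.round((cloud.x - offsets[0]) / scale).astype(np.int32)
        rec["Y"] = np.round((cloud.y - offsets[1]) / scale).astype(np.int32)
        rec["Z"] = np.round((cloud.z - offsets[2]) / scale).astype(np.int32)
        nret = np.ones(n, dtype=np.uint8)
        rec["flags"] = (cloud.return_number & 0x07) | ((nret & 0x07) << 3)
        rec["classification"] = cloud.classification
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


def read_las(path) -> PointCloud:
    """Read a LAS 1.x file (point formats 0-3) into a PointCloud."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER_SIZE:
        raise ValueError(f"{path}: truncated LAS header")
    fields = struct.unpack(_HEADER_FMT, raw[:_HEADER_SIZE])
    if fields[0] != b"LASF":
        raise ValueError(f"{path}: not a LAS file (bad signature)")
    ver_major, ver_minor = fields[4], fields[5]
    if ver_major != 1:
        raise ValueError(f"{path}: unsupported LAS version "
                         f"{ver_major}.{ver_minor}")
    offset_to_points = fields[11]
    point_format = fields[13] & 0x3F
    record_length = fields[14]
    n = fields[15]
    if point_format not in _POINT_RECORD_LENGTHS:
        raise ValueError(f"{path}: unsupported point format {point_format}")
    if record_length < 20:
        raise ValueError(f"{path}: implausible point record length "
                         f"{record_length}")
    sx, sy, sz, ox, oy, oz = fields[21:27]

    body = raw[offset_to_points:offset_to_points + n * record_length]
    if len(body) < n * record_length:
        raise ValueError(f"{path}: point data truncated")
    dtype = dict(_POINT0_DTYPE, itemsize=record_length)
    rec = np.frombuffer(body, dtype=np.dtype(dtype), count=n)
    return PointCloud(
        x=rec["X"] * sx + ox, y=rec["Y"] * sy + oy, z=rec["Z"] * sz + oz,
        return_number=(rec["flags"] & 0x07).astype(np.uint8),
        classification=rec["classification"].copy(),
    )
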