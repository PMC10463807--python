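"""Minimal reader/writer for the ImageJ ``.roi`` binary format (polygon type).

Only the subset needed to exchange fiber/section/cell outlines with
Fiji/ImageJ is implemented: polygon ROIs with 0-based integer vertex
coordinates, stored big-endian.  Vertices are truncated to integers on
encoding, which is the precision the format itself stores.

Layout of the 64-byte header (offsets in bytes, all big-endian):

====== ======================= =====================================
0-3    magic                   ``b"Iout"``
4-5    version (int16)         227 written here
6      roi type (int8)         0 = polygon
8-15   top,left,bottom,right   int16 bounding box
16-17  n coordinates (int16)
64..   x offsets then y offsets, int16 relative to (left, top)
====== ======================= =====================================
"""

from __future__ import annotations

import struct
import zipfile
from typing import Iterable, Sequence

import numpy as np

MAGIC = b"Iout"
VERSION = 227
TYPE_POLYGON = 0
HEADER_SIZE = 64


class RoiFormatError(ValueError):
    """Raised when bytes do not parse as a supported ImageJ ROI."""


def encode_polygon(vertices: Sequence[Sequence[float]]) -> bytes:
    """Encode a closed polygon as an ImageJ ``.roi`` record.

    ``vertices`` is an (n, 2) sequence of (x, y) pixel coordinates; a
    repeated closing vertex is dropped.  Coordinates are truncated to
    integers.
    """
    pts = np.asarray(vertices, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise RoiFormatError("vertices must be an (n, 2) array of (x, y)")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise RoiFormatError("polygon needs at least 3 vertices")
    xs = pts[:, 0].astype(np.int32)
    ys = pts[:, 1].astype(np.int32)
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()), int(ys.max())
    n = len(pts)

    header = bytearray(HEADER_SIZE)
    header[0:4] = MAGIC
    struct.pack_into(">h", header, 4, VERSION)
    header[6] = TYPE_POLYGON
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)

    body = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))
    return bytes(header) + body


def decode_polygon(data: bytes) -> np.ndarray:
    """Decode an ImageJ ``.roi`` record back into an (n, 2) int array."""
    if len(data) < HEADER_SIZE or data[0:4] != MAGIC:
        raise RoiFormatError("not an ImageJ ROI record")
    roi_type = data[6]
    if roi_type != TYPE_POLYGON:
        raise RoiFormatError(f"unsupported ROI type {roi_type} (only polygon)")
    top, left, _bottom, _right = struct.unpack_from(">4h", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    xs = np.array(struct.unpack_from(f">{n}h", data, HEADER_SIZE)) + left
    ys = np.array(struct.unpack_from(f">{n}h", data, HEADER_SIZE + 2 * n)) + top
    return np.stack([xs, ys], axis=1)


def write_roi_zip(path, named_polygons: Iterable[tuple[str, Sequence]]) -> list[str]:
    """Write ``(name, vertices)`` pairs into a Fiji-compatible ROI zip.

    Returns the entry names written.  Degenerate polygons raise at the
    encoding level; callers decide whether to skip them.
    """
    written = []
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, verts in named_polygons:
            entry = name if name.endswith(".roi") else name + ".roi"
            zf.writestr(entry, encode_polygon(verts))
            written.append(entry)
    return written


def read_roi_zip(path) -> dict[str, np.ndarray]:
    """Read every polygon ROI in a zip archive, keyed by entry stem."""
    out: dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path) as zf:
        for entry in zf.namelist():
            stem = entry[:-4] if entry.endswith(".roi") else entry
            out[stem] = decode_polygon(zf.read(entry))
    return out
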