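"""Minimal reader/writer for ImageJ .roi polyline files.

Implements only the subset needed for cord paths: the classic big-endian
"Iout" format with 16-bit integer vertex coordinates, ROI types polyline (5),
freeline (4) and polygon (0). Subpixel (float) coordinate blocks are read
when the header flags them.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_MAGIC = b"Iout"
_HEADER_SIZE = 64
_POLYLINE_TYPES = {0, 4, 5, 7, 8}  # polygon, freeline, polyline, freehand, traced
_SUBPIXEL_FLAG = 128


def read_polyline_roi(path: str | Path) -> np.ndarray:
    """Return the (n, 2) float array of (x, y) vertices of a polyline ROI."""
    data = Path(path).read_bytes()
    if len(data) < _HEADER_SIZE or data[:4] != _MAGIC:
        raise ValueError("not an ImageJ ROI file (bad magic)")
    roi_type = data[6]
    if roi_type not in _POLYLINE_TYPES:
        raise ValueError(f"ROI type {roi_type} is not a polyline/polygon")
    top, left, _bottom, _right, n = struct.unpack(">5h", data[8:18])
    if n < 1:
        raise ValueError("ROI contains no coordinates")
    options = struct.unpack(">h", data[50:52])[0]
    if options & _SUBPIXEL_FLAG:
        off = _HEADER_SIZE + 4 * n  # float block follows the int16 block
        xs = np.frombuffer(data, dtype=">f4", count=n, offset=off)
        ys = np.frombuffer(data, dtype=">f4", count=n, offset=off + 4 * n)
        return np.column_stack([xs, ys]).astype(float)
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=_HEADER_SIZE)
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=_HEADER_SIZE + 2 * n)
    return np.column_stack([xs + left, ys + top]).astype(float)


def write_polyline_roi(path: str | Path, vertices: np.ndarray) -> None:
    """Write (x, y) vertices as an ImageJ polyline .roi (int16 coordinates)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("need an (n, 2) array with n >= 2")
    xi = np.round(v[:, 0]).astype(int)
    yi = np.round(v[:, 1]).astype(int)
    left, top = int(xi.min()), int(yi.min())
    right, bottom = int(xi.max()), int(yi.max())
    n = len(v)
    header = bytearray(_HEADER_SIZE)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, 227)  # version
    header[6] = 5  # polyline
    struct.pack_into(">5h", header, 8, top, left, bottom, right, n)
    body = (
        (xi - left).astype(">i2").tobytes() + (yi - top).astype(">i2").tobytes()
    )
    Path(path).write_bytes(bytes(header) + body)
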