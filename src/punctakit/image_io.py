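"""Calibrated images, cord paths, and linescan extraction.

Conventions used throughout the package:

* pixel coordinates are 0-based, with positions at pixel centers;
* ``(x, y)`` order for path vertices (column, row), matching ImageJ;
* arc length is measured in microns from the first path vertex;
* the linescan samples the path at 1-pixel arc-length steps and averages
  ``line_width_px`` bilinear samples along the local perpendicular.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import map_coordinates

from punctakit._imagej_roi import read_polyline_roi

__all__ = [
    "CalibratedImage",
    "CordPath",
    "IntensityProfile",
    "max_project",
    "read_tiff_stack",
    "read_cord_path",
    "extract_profile",
    "write_profile_csv",
]

DEFAULT_LINE_WIDTH_PX = 3


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D intensity image with spatial calibration.

    Parameters
    ----------
    pixels
        2D array of non-negative, finite intensities (arbitrary units).
    um_per_px
        Pixel size in microns; must be positive.
    source_id
        Opaque identifier (file name, animal ID, ...).
    """

    pixels: np.ndarray
    um_per_px: float
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("pixels must be a 2D array with >= 2 rows and columns")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("intensities must be finite and >= 0")
        if not (np.isfinite(self.um_per_px) and self.um_per_px > 0):
            raise ValueError("um_per_px must be a positive finite scalar")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class CordPath:
    """Ordered polyline of (x, y) pixel vertices defining the neurite axis."""

    vertices: np.ndarray
    line_width_px: int = DEFAULT_LINE_WIDTH_PX

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("degenerate path: need >= 2 (x, y) vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        if self.line_width_px < 1:
            raise ValueError("line_width_px must be a positive integer")
        object.__setattr__(self, "vertices", v)

    @property
    def length_px(self) -> float:
        """Total polyline length in pixels."""
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def reversed(self) -> "CordPath":
        return replace(self, vertices=self.vertices[::-1].copy())


@dataclass(frozen=True)
class IntensityProfile:
    """1D calibrated intensity trace along the cord.

    ``positions`` are arc-length positions in microns starting at 0, spaced
    by ``um_per_px``; ``intensities`` are in arbitrary units.
    """

    positions: np.ndarray
    intensities: np.ndarray
    um_per_px: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or inten.ndim != 1 or pos.size != inten.size or pos.size < 2:
            raise ValueError("positions and intensities must be same-length 1D arrays (>= 2)")
        if abs(pos[0]) > 1e-9:
            raise ValueError("positions must start at 0")
        step = np.diff(pos)
        if np.any(step <= 0) or np.any(np.abs(step - self.um_per_px) > 1e-6 * self.um_per_px):
            raise ValueError("positions must increase by um_per_px")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def span_um(self) -> float:
        """Analyzed cord length in microns (first to last sample)."""
        return float(self.positions[-1] - self.positions[0])

    def with_intensities(self, intensities: np.ndarray) -> "IntensityProfile":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


def max_project(stack: Sequence[np.ndarray]) -> np.ndarray:
    """Maximum-intensity projection of a Z-series stack.

    Each output pixel is the maximum of that pixel across all slices.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    arrays = [np.asarray(s) for s in stack]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("ragged stack: slices have mismatched shapes")
    out = arrays[0].astype(float, copy=True)
    for a in arrays[1:]:
        np.maximum(out, a, out=out)
    return out


def _um_per_px_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Derive microns/pixel from TIFF resolution tags, if present.

    The XResolution rational stores pixels per ResolutionUnit. Microscopy
    TIFFs (ImageJ convention) typically use unit NONE with pixels/micron;
    inch and centimeter units are converted.
    """
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0 or den == 0 or (num, den) == (1, 1):
        return None  # (1, 1) is the writers' "no calibration" placeholder
    px_per_unit = num / den
    unit_tag = page.tags.get("ResolutionUnit")
    unit = getattr(unit_tag, "value", 1)
    unit = int(unit) if not isinstance(unit, int) else unit
    if unit == 2:  # inch
        return 25400.0 / px_per_unit
    if unit == 3:  # centimeter
        return 10000.0 / px_per_unit
    # NONE: ImageJ stores the calibrated unit in its metadata; assume micron
    ij = tif.imagej_metadata or {}
    if ij.get("unit") in (None, "um", "micron", "microns", "µm"):
        return 1.0 / px_per_unit
    return None


def read_tiff_stack(path: str | Path) -> tuple[list[np.ndarray], float | None]:
    """Read a grayscale TIFF as a list of 2D pages plus optional calibration.

    Returns ``(pages, um_per_px)`` where ``um_per_px`` is ``None`` when the
    file carries no usable resolution tag (the caller must then supply the
    calibration explicitly).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            um_per_px = _um_per_px_from_tiff(tif)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise ValueError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        pages = [data]
    elif data.ndim == 3 and data.shape[-1] not in (3, 4):
        pages = [data[i] for i in range(data.shape[0])]
    else:
        raise ValueError(f"cannot read TIFF {path}: expected grayscale pages, got shape {data.shape}")
    return [np.asarray(p, dtype=float) for p in pages], um_per_px


def read_cord_path(
    path: str | Path,
    dialect: str = "csv",
    line_width_px: int = DEFAULT_LINE_WIDTH_PX,
) -> CordPath:
    """Read a cord path from a CSV (columns x,y) or an ImageJ .roi polyline."""
    path = Path(path)
    if dialect == "csv":
        try:
            df = pd.read_csv(path)
            vertices = df[["x", "y"]].to_numpy(dtype=float)
        except (KeyError, ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"cannot parse cord path {path} as csv: {exc}") from exc
    elif dialect == "imagej_roi":
        try:
            vertices = read_polyline_roi(path)
        except ValueError as exc:
            raise ValueError(f"cannot parse cord path {path} as imagej_roi: {exc}") from exc
    else:
        raise ValueError(f"unknown cord-path dialect {dialect!r}")
    if vertices.shape[0] < 2:
        raise ValueError(f"degenerate path in {path}: need >= 2 vertices")
    return CordPath(vertices=vertices, line_width_px=line_width_px)


def _sample_points(path: CordPath) -> tuple[np.ndarray, np.ndarray]:
    """Resample the polyline at 1-pixel arc-length steps.

    Returns ``(points, tangents)``: (n, 2) arrays of (x, y) sample positions
    and unit tangent vectors. The final sample sits at the last vertex only
    when the total length is an integer number of pixels; otherwise the last
    partial step is dropped so that spacing stays exactly 1 px.
    """
    v = path.vertices
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.arange(0.0, total + 1e-9, 1.0)
    x = np.interp(s, cum, v[:, 0])
    y = np.interp(s, cum, v[:, 1])
    # tangent of the segment each sample falls in (last sample: last segment)
    idx = np.minimum(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
    idx = np.maximum(idx, 0)
    tangents = seg[idx] / seg_len[idx, None]
    return np.column_stack([x, y]), tangents


def extract_profile(image: CalibratedImage, path: CordPath) -> IntensityProfile:
    """Extract the linescan intensity profile along a cord path.

    The path is sampled every pixel of arc length; at each sample the
    intensity is the mean of ``line_width_px`` bilinear interpolations spaced
    1 px apart along the local perpendicular, centered on the path.
    """
    points, tangents = _sample_points(path)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    w = path.line_width_px
    offsets = np.arange(w, dtype=float) - (w - 1) / 2.0

    h, wid = image.pixels.shape
    # all sampled coordinates: (n_samples, w, 2)
    coords = points[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    xs = coords[..., 0]
    ys = coords[..., 1]
    out_of_bounds = (xs < 0) | (xs > wid - 1) | (ys < 0) | (ys > h - 1)
    if np.any(out_of_bounds):
        bad = int(np.argmax(np.any(out_of_bounds, axis=1)))
        raise ValueError(
            f"cord path (with line width {w}) exits image bounds near sample "
            f"{bad} at (x={points[bad, 0]:.1f}, y={points[bad, 1]:.1f})"
        )
    # map_coordinates takes (row, col) = (y, x)
    values = map_coordinates(
        image.pixels, [ys.ravel(), xs.ravel()], order=1, mode="nearest"
    ).reshape(xs.shape)
    intensities = values.mean(axis=1)
    positions = np.arange(len(intensities)) * image.um_per_px
    return IntensityProfile(positions=positions, intensities=intensities, um_per_px=image.um_per_px)


def write_profile_csv(profile: IntensityProfile, path: str | Path) -> None:
    """Export a profile as CSV with columns position_um, intensity."""
    pd.DataFrame(
        {"position_um": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, index=False)


def read_profile_csv(path: str | Path, um_per_px: float | None = None) -> IntensityProfile:
    """Read a profile CSV (columns position_um, intensity)."""
    df = pd.read_csv(path)
    try:
        pos = df["position_um"].to_numpy(dtype=float)
        inten = df["intensity"].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"profile CSV {path} missing column {exc}") from exc
    if um_per_px is None:
        if len(pos) < 2:
            raise ValueError(f"profile CSV {path} too short to infer calibration")
        um_per_px = float(pos[1] - pos[0])
    return IntensityProfile(positions=pos, intensities=inten, um_per_px=um_per_px)
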