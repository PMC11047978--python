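"""ROI polygons delineating individual PNNs.

ROIs are drawn manually in practice, so they are inputs here: either the
package's documented JSON polygon format or ImageJ ``.roi`` / ``.zip``
files (polygon, freehand, traced and rectangle types).  Vertices are in
pixel coordinates ``(x, y)``; areas are converted to µm² through the
pixel size.  Pixel membership uses the pixel-centre, even-odd rule.
"""

from __future__ import annotations

import json
import struct
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

from .geometry import ParameterError

__all__ = ["RoiPolygon", "RoiFormatError", "read_rois", "write_rois_json",
           "write_imagej_roi"]


class RoiFormatError(ValueError):
    """Raised for malformed or geometrically invalid ROI files."""


@dataclass
class RoiPolygon:
    """A simple polygon ROI with physical calibration.

    ``vertices`` is an (N, 2) array of ``(x, y)`` pixel coordinates.
    """

    roi_id: str
    vertices: np.ndarray
    pixel_size: float
    subregion: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise RoiFormatError(
                f"ROI {self.roi_id!r}: a polygon needs >= 3 (x, y) vertices")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        poly = ShapelyPolygon(v)
        if not poly.is_simple or poly.area <= 0:
            raise RoiFormatError(
                f"ROI {self.roi_id!r} is self-intersecting or degenerate")
        self.vertices = v

    @property
    def area_px(self) -> float:
        """Shoelace area in pixel² units."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    @property
    def area(self) -> float:
        """Polygon area in µm²."""
        return self.area_px * self.pixel_size**2

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centres fall inside the polygon."""
        ny, nx = shape
        yy, xx = np.mgrid[0:ny, 0:nx]
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        inside = MplPath(self.vertices).contains_points(pts)
        return inside.reshape(ny, nx)

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        return MplPath(self.vertices).contains_points(np.atleast_2d(xy))

    def centroid(self) -> tuple[float, float]:
        c = ShapelyPolygon(self.vertices).centroid
        return (c.x, c.y)


def write_rois_json(rois: list[RoiPolygon], path) -> None:
    payload = {
        "pixel_size_um": rois[0].pixel_size if rois else None,
        "rois": [
            {
                "roi_id": r.roi_id,
                "subregion": r.subregion,
                "vertices": r.vertices.tolist(),
            }
            for r in rois
        ],
    }
    FsPath(path).write_text(json.dumps(payload, indent=1))


# --- minimal ImageJ .roi reader --------------------------------------------
# Binary layout per ImageJ's RoiDecoder: 4-byte magic "Iout", version,
# type byte, bounding box (top, left, bottom, right) as int16,
# n_coordinates as int16, then relative int16 x[] and y[] arrays at
# offset 64 for polygon-like types.

_IJ_POLYGON, _IJ_RECT, _IJ_OVAL, _IJ_FREEHAND, _IJ_TRACED = 0, 1, 2, 7, 8


def _decode_imagej_roi(buf: bytes, name: str, pixel_size: float) -> RoiPolygon:
    if len(buf) < 64 or buf[:4] != b"Iout":
        raise RoiFormatError(f"{name}: not an ImageJ ROI file")
    roi_type = buf[6]
    top, left, bottom, right = struct.unpack(">4h", buf[8:16])
    n = struct.unpack(">h", buf[16:18])[0]
    if roi_type == _IJ_RECT:
        verts = [(left, top), (right, top), (right, bottom), (left, bottom)]
    elif roi_type == _IJ_OVAL:
        cx, cy = (left + right) / 2.0, (top + bottom) / 2.0
        rx, ry = (right - left) / 2.0, (bottom - top) / 2.0
        t = np.linspace(0, 2 * np.pi, 33)[:-1]
        verts = np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])
    elif roi_type in (_IJ_POLYGON, _IJ_FREEHAND, _IJ_TRACED):
        if n <= 0 or len(buf) < 64 + 4 * n:
            raise RoiFormatError(f"{name}: truncated coordinate block")
        xs = np.frombuffer(buf, dtype=">i2", count=n, offset=64).astype(float)
        ys = np.frombuffer(buf, dtype=">i2", count=n, offset=64 + 2 * n).astype(float)
        verts = np.column_stack([xs + left, ys + top])
    else:
        raise RoiFormatError(f"{name}: unsupported ImageJ ROI type {roi_type}")
    return RoiPolygon(name, np.asarray(verts, dtype=float), pixel_size)


def write_imagej_roi(roi: RoiPolygon, path, rect: bool = False) -> None:
    """Write a minimal ImageJ ``.roi`` file (integer coordinates)."""
    v = np.round(roi.vertices).astype(int)
    left, top = int(v[:, 0].min()), int(v[:, 1].min())
    right, bottom = int(v[:, 0].max()), int(v[:, 1].max())
    header = bytearray(64)
    header[:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    if rect:
        header[6] = _IJ_RECT
        n = 0
        body = b""
    else:
        header[6] = _IJ_POLYGON
        n = len(v)
        body = (v[:, 0] - left).astype(">i2").tobytes() + \
               (v[:, 1] - top).astype(">i2").tobytes()
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    FsPath(path).write_bytes(bytes(header) + body)


def read_rois(path, pixel_size: float | None = None) -> list[RoiPolygon]:
    """Read ROIs from JSON, ImageJ ``.roi`` or an ImageJ ``.zip`` bundle.

    JSON files carry their own ``pixel_size_um``; ImageJ files do not, so
    ``pixel_size`` must be supplied for them.  An empty ROI list is
    returned with a warning, never an error.
    """
    p = FsPath(path)
    suffix = p.suffix.lower()
    if suffix == ".json":
        try:
            payload = json.loads(p.read_text())
        except json.JSONDecodeError as exc:
            raise RoiFormatError(f"{p}: invalid JSON ({exc})") from exc
        ps = payload.get("pixel_size_um") or pixel_size
        entries = payload.get("rois", [])
        if not entries:
            warnings.warn(f"{p}: no ROIs found", stacklevel=2)
            return []
        if ps is None:
            raise RoiFormatError(f"{p}: pixel_size_um missing; supply calibration")
        return [
            RoiPolygon(str(e.get("roi_id", i)), np.asarray(e["vertices"], float),
                       float(ps), e.get("subregion"))
            for i, e in enumerate(entries)
        ]
    if pixel_size is None:
        raise RoiFormatError(
            f"{p}: ImageJ ROI files carry no calibration; supply pixel_size")
    if suffix == ".roi":
        return [_decode_imagej_roi(p.read_bytes(), p.stem, pixel_size)]
    if suffix == ".zip":
        rois = []
        with zipfile.ZipFile(p) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    rois.append(_decode_imagej_roi(
                        zf.read(name), FsPath(name).stem, pixel_size))
        if not rois:
            warnings.warn(f"{p}: no ROIs found in archive", stacklevel=2)
        return rois
    raise RoiFormatError(f"{p}: unsupported ROI file type {suffix!r}")
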